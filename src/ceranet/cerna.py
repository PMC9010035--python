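"""Dual expression/sequence ceRNA screen.

Knocking down a sponge lncRNA frees the miRNAs it sequesters (up) which then
repress their mRNA targets (down) — the down-up-down pattern.  The screen
combines two independent evidence channels:

* expression: upregulated DE miRNAs eligible to link the downregulated
  sponge lncRNA with at least one downregulated validated mRNA;
* sequence: miRNAs with at least one canonical seed site (6mer, 7mer-A1,
  7mer-m8 or 8mer) in a validated mRNA's 3'UTR.

Candidates in both channels, minus upregulated control-group miRNAs, form
the final sponge set; the lncRNA-side seed matches (sponge sites) are
computed and reported as supporting evidence but are not required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .diffexp import DEProfile
from .networks import TypedNetwork
from .specificity import FeatureSet

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # most to least specific

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CernaError(ValueError):
    pass


@dataclass(frozen=True)
class SeedMatch:
    """One canonical seed site in a target sequence.

    ``position`` is the 0-based offset of the full site (including the m8
    match for 7mer-m8/8mer sites) in the target, which is read 5'->3'.
    """

    mirna_id: str
    target_id: str
    site_type: str
    position: int


def _normalize(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise CernaError(f"{what}: non-ACGU/ACGT characters {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_match(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "mirna",
    target_id: str = "target",
) -> List[SeedMatch]:
    """Scan a target for canonical seed sites of one miRNA.

    Site classes (target written 5'->3'; seed = miRNA nucleotides 2-8):
    6mer = reverse complement of nt 2-7; 7mer-m8 = rc of nt 2-8;
    7mer-A1 = rc of nt 2-7 followed by A; 8mer = rc of nt 2-8 followed by A.
    Each seed-pairing location is reported once with its most specific class.
    """
    mir = _normalize(mirna_seq, "miRNA")
    if len(mir) < 8:
        raise CernaError("miRNA must be at least 8 nt")
    tgt = _normalize(target_seq, "target")
    core = _revcomp(mir[1:7])  # rc of seed nt 2-7, the 6mer match
    m8 = _revcomp(mir[7])  # target base pairing miRNA nt 8, 5' of the core
    out: List[SeedMatch] = []
    j = tgt.find(core)
    while j != -1:
        has_m8 = j > 0 and tgt[j - 1] == m8
        has_a1 = j + 6 < len(tgt) and tgt[j + 6] == "A"
        if has_m8 and has_a1:
            site, pos = "8mer", j - 1
        elif has_m8:
            site, pos = "7mer-m8", j - 1
        elif has_a1:
            site, pos = "7mer-A1", j
        else:
            site, pos = "6mer", j
        out.append(SeedMatch(mirna_id, target_id, site, pos))
        j = tgt.find(core, j + 1)
    return out


def expression_triads(
    kd_lnc: FeatureSet,
    kd_mirna_profile: DEProfile | FeatureSet,
    validated_mrnas: Mapping[str, str],
    target_lnc: str | None = None,
) -> Set[str]:
    """Upregulated DE miRNAs satisfying the down-up-down pattern.

    The pattern requires the sponge lncRNA down in the knockdown profile and
    at least one validated mRNA with direction "down"; validated directions
    are explicit inputs (e.g. from qPCR).  When the pattern is unsatisfiable
    the result is empty.
    """
    if not validated_mrnas:
        raise CernaError("validated_mrnas must be nonempty")
    if target_lnc is not None:
        lnc_down = kd_lnc.members.get(target_lnc) == "down"
    else:
        lnc_down = any(d == "down" for d in kd_lnc.members.values())
    if not lnc_down:
        return set()
    if not any(d == "down" for d in validated_mrnas.values()):
        return set()
    if isinstance(kd_mirna_profile, FeatureSet):
        members = kd_mirna_profile.members
    else:
        table = kd_mirna_profile.features("miRNA")
        members = dict(zip(table.index, table["direction"]))
    return {m for m, d in members.items() if d == "up"}


def mirna_target_matches(
    mirna_fasta: Mapping[str, str],
    target_fasta: Mapping[str, str],
    target_ids: Sequence[str] | None = None,
) -> Dict[str, List[SeedMatch]]:
    """All seed matches of each miRNA against each target, keyed by target."""
    ids = list(target_ids) if target_ids is not None else sorted(target_fasta)
    out: Dict[str, List[SeedMatch]] = {}
    for tid in ids:
        if tid not in target_fasta:
            raise CernaError(f"missing sequence for target {tid!r}")
        hits: List[SeedMatch] = []
        for mid in sorted(mirna_fasta):
            hits.extend(seed_match(mirna_fasta[mid], target_fasta[tid], mid, tid))
        out[tid] = hits
    return out


def union_candidates(per_gene: Mapping[str, Iterable[str]]) -> Set[str]:
    """De-duplicated union of per-gene miRNA candidate sets."""
    out: Set[str] = set()
    for gene in per_gene:
        out |= set(per_gene[gene])
    return out


def sequence_candidates(
    validated_mrnas: Sequence[str],
    mirna_fasta: Mapping[str, str],
    utr_fasta: Mapping[str, str],
) -> Set[str]:
    """miRNAs with >=1 seed site in at least one validated gene's 3'UTR."""
    for mid in mirna_fasta:
        if not mirna_fasta[mid]:
            raise CernaError(f"missing sequence for miRNA {mid!r}")
    matches = mirna_target_matches(mirna_fasta, utr_fasta, validated_mrnas)
    per_gene = {
        gene: {h.mirna_id for h in hits} for gene, hits in matches.items()
    }
    return union_candidates(per_gene)


def dual_screen(
    expr_set: Iterable[str],
    seq_set: Iterable[str],
    control_up: Iterable[str],
) -> Set[str]:
    """(expression candidates AND sequence candidates) minus control-up miRNAs."""
    return (set(expr_set) & set(seq_set)) - set(control_up)


def assemble_cerna_network(
    final_mirnas: Iterable[str],
    lncrna_id: str,
    target_matches: Mapping[str, Iterable[str]],
    lncrna_matches: Iterable[str] = (),
) -> TypedNetwork:
    """Star-of-triads network for the surviving miRNAs.

    ``target_matches`` maps each final miRNA to the validated mRNAs it
    seed-matches; edges are lncRNA-miRNA (type ``cerna``) and miRNA-mRNA
    (type ``seed_match``).  ``lncrna_matches`` flags miRNAs with a sponge
    site in the lncRNA itself (stored as an edge attribute).
    """
    sponge_evidence = set(lncrna_matches)
    net = TypedNetwork()
    mirnas = sorted(set(final_mirnas))
    if mirnas:
        net.add_node(lncrna_id, "lncRNA")
    for mid in mirnas:
        net.add_node(mid, "miRNA")
        net.add_edge(
            lncrna_id, mid, "cerna", sponge_site=mid in sponge_evidence
        )
        for gid in sorted(set(target_matches.get(mid, ()))):
            net.add_node(gid, "mRNA")
            net.add_edge(mid, gid, "seed_match")
    return net


def triads_of(net: TypedNetwork, lncrna_id: str) -> Set[Tuple[str, str, str]]:
    """Enumerate (lncRNA, miRNA, mRNA) triads present in a ceRNA network."""
    out = set()
    if lncrna_id not in net.graph:
        return out
    for mid in net.graph.neighbors(lncrna_id):
        if net.graph.edges[lncrna_id, mid].get("type") != "cerna":
            continue
        for gid in net.graph.neighbors(mid):
            if net.graph.edges[mid, gid].get("type") == "seed_match":
                out.add((lncrna_id, mid, gid))
    return out
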