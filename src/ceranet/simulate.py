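"""Synthetic five-sample knockdown dataset with planted ground truth.

Emulates the study design the pipeline screens: a blank reference (S0), two
targeted-knockdown samples (S1, S2) and two nonspecific/empty-vector control
samples (S3, S4).  The generator plants every signal the downstream stages
look for, and records it:

* a targeted sponge lncRNA knocked down in S1-S2;
* generic DE features with a +/- ``planted_log2fc`` shift in S1 AND S2;
* nonspecific effects shared by S3-S4, partially overlapping the planted
  knockdown set so overlap removal is exercised;
* lncRNA loci placed as natural-antisense (exon-overlapping, opposite
  strand) or intronic-antisense (intron-contained, opposite strand)
  partners of specific mRNAs; the rest far from any mRNA;
* a scale-free (preferential-attachment) PPI over mRNA products plus extra
  proteins;
* miRNA/3'UTR/lncRNA sequences with planted 8mer seed sites realizing
  down-up-down ceRNA triads, with chance seed matches scrubbed so sequence
  evidence is exactly the planted set.

Counts are negative binomial around lognormal baseline means with a fixed
dispersion phi (variance = mu + phi mu^2).  All randomness flows from one
integer seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneAnnotation
from .cerna import _normalize, _revcomp, seed_match
from .diffexp import ExpressionMatrix

KNOCKDOWN_CONTRAST = "knockdown"
NONSPECIFIC_CONTRAST = "nonspecific"

SAMPLES = ("S0", "S1", "S2", "S3", "S4")
KD_SAMPLES = ("S1", "S2")
CTRL_SAMPLES = ("S3", "S4")


class SimulationError(ValueError):
    pass


class PlacementError(SimulationError):
    """Chromosome too short to place all genes without unplanned overlap."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic five-sample knockdown design.

    The defaults are the study conditions the pipeline is exercised under;
    see docs/methods.md for the rationale behind each value.
    """

    n_mrna: int = 200
    n_lncrna: int = 24
    n_mirna: int = 200
    n_protein_extra: int = 150
    n_planted_de: int = 40
    planted_log2fc: float = 2.0
    knockdown_log2fc: float = 3.5  # targeted lncRNA knockdown depth
    triad_log2fc: float = 3.5  # planted triad miRNA (up) / mRNA (down) effects
    nonspecific_fraction: float = 0.1
    nonspecific_overlap: int = 4  # planted DE features also hit in controls
    baseline_mean: float = 300.0  # lognormal median of per-feature means
    baseline_sigma: float = 1.0
    dispersion: float = 0.16  # NB phi: variance = mu + phi mu^2
    n_planted_triads: int = 3
    antisense_fraction: float = 0.5
    proximity_window_bp: int = 10_000
    utr_length: int = 300
    lnc_transcript_length: int = 600
    screen_seed_collisions: bool = True
    chrom_length: Optional[int] = None  # None = auto-size
    seed: int = 42

    def __post_init__(self) -> None:
        counts = (
            self.n_mrna,
            self.n_lncrna,
            self.n_mirna,
            self.n_protein_extra,
            self.n_planted_de,
            self.n_planted_triads,
            self.nonspecific_overlap,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("all counts must be >= 0")
        if self.n_planted_de > self.n_mrna + self.n_lncrna:
            raise SimulationError("n_planted_de exceeds number of mRNA+lncRNA features")
        if self.n_planted_triads > min(self.n_lncrna, self.n_mirna, self.n_mrna):
            raise SimulationError("n_planted_triads exceeds available features")
        for frac in (self.nonspecific_fraction, self.antisense_fraction):
            if not (0 <= frac <= 1):
                raise SimulationError("fractions must lie in [0, 1]")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.proximity_window_bp <= 0:
            raise SimulationError("proximity_window_bp must be positive")


@dataclass
class GroundTruth:
    """Planted signals, recorded as the generator places them."""

    de_features: Set[Tuple[str, str, str]] = field(default_factory=set)
    antisense_pairs: Set[Tuple[str, str, str]] = field(default_factory=set)
    triads: Set[Tuple[str, str, str]] = field(default_factory=set)
    dominant_genes: Set[str] = field(default_factory=set)
    target_lncrna: str = ""
    validated_mrnas: Dict[str, str] = field(default_factory=dict)
    planted_sites: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def knockdown_de(self) -> Set[Tuple[str, str]]:
        return {
            (f, d) for f, d, c in self.de_features if c == KNOCKDOWN_CONTRAST
        }

    def nonspecific_de(self) -> Set[Tuple[str, str]]:
        return {
            (f, d) for f, d, c in self.de_features if c == NONSPECIFIC_CONTRAST
        }


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    annotation: AnnotationSet
    counts: ExpressionMatrix
    ppi: List[Tuple[str, str]]
    mirna_sequences: Dict[str, str]
    utr_sequences: Dict[str, str]
    lncrna_sequences: Dict[str, str]
    gene_sets: Dict[str, List[str]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation

_MRNA_EXONS = ((0, 600), (1600, 2000))  # relative to gene start; intron [600,1600)
_GENE_SPACING_FACTOR = 3  # mRNA blocks sit >= 3 windows apart


def simulate_annotation(
    config: SimulationConfig,
) -> Tuple[AnnotationSet, GroundTruth]:
    """Place mRNA, lncRNA and miRNA loci on one synthetic chromosome.

    A fraction ``antisense_fraction`` of lncRNAs becomes antisense partners
    of distinct mRNAs, alternating natural (exon-overlapping) and intronic
    (intron-contained) classes; the first lncRNA is the knockdown target and
    is placed as a natural antisense transcript when any antisense lncRNAs
    are requested.  The remaining lncRNAs sit at least twice the proximity
    window away from every mRNA.
    """
    ann = AnnotationSet()
    truth = GroundTruth()
    chrom = "chrS"
    window = config.proximity_window_bp
    spacing = _GENE_SPACING_FACTOR * window
    glen = _MRNA_EXONS[-1][1]

    n_anti = int(round(config.antisense_fraction * config.n_lncrna))
    n_anti = min(n_anti, config.n_mrna, config.n_lncrna)

    mrna_ids = [f"G{i:03d}" for i in range(config.n_mrna)]
    if config.n_lncrna > 0:
        lnc_ids = ["LNC_TARGET"] + [f"L{i:03d}" for i in range(1, config.n_lncrna)]
    else:
        lnc_ids = []
    mir_ids = [f"MIR{i:03d}" for i in range(config.n_mirna)]

    pos = 10_000
    for i, gid in enumerate(mrna_ids):
        exons = tuple((pos + s, pos + e) for s, e in _MRNA_EXONS)
        ann.add(
            GeneAnnotation(gid, chrom, "+", pos, pos + glen, exons, "mRNA")
        )
        if i < n_anti:
            lid = lnc_ids[i]
            if i % 2 == 0:  # natural antisense: overlap exon 1, opposite strand
                s, e = pos + 100, pos + 500
                cls = "antisense_natural"
            else:  # intronic antisense: fully inside the intron
                s, e = pos + 700, pos + 1400
                cls = "antisense_intronic"
            ann.add(GeneAnnotation(lid, chrom, "-", s, e, ((s, e),), "lncRNA"))
            truth.antisense_pairs.add((lid, gid, cls))
        pos += glen + spacing

    # distal lncRNAs: >= 2 windows from any mRNA
    pos += 2 * window
    for lid in lnc_ids[n_anti:]:
        ann.add(
            GeneAnnotation(lid, chrom, "-", pos, pos + 500, ((pos, pos + 500),), "lncRNA")
        )
        pos += 500 + 2 * window

    for mid in mir_ids:
        ann.add(
            GeneAnnotation(mid, chrom, "+", pos, pos + 80, ((pos, pos + 80),), "miRNA")
        )
        pos += 80 + 1000

    if config.chrom_length is not None and pos > config.chrom_length:
        raise PlacementError(
            f"chromosome length {config.chrom_length} too short: need {pos} bp "
            f"to place all genes without unplanned overlap"
        )
    truth.target_lncrna = lnc_ids[0] if lnc_ids else ""
    return ann, truth


# ---------------------------------------------------------------------------
# counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def _plan_effects(
    annotation: AnnotationSet, config: SimulationConfig, truth: GroundTruth,
    rng: np.random.Generator,
) -> Tuple[Dict[str, Tuple[str, float]], Dict[str, Tuple[str, float]]]:
    """Assign per-feature knockdown and nonspecific effects.

    Returns two maps feature_id -> (direction, log2fc magnitude), one for the
    knockdown samples (S1, S2) and one for the control samples (S3, S4), and
    records everything in ``truth``.
    """
    mrna_ids = annotation.ids("mRNA")
    lnc_ids = annotation.ids("lncRNA")
    mir_ids = annotation.ids("miRNA")
    target = truth.target_lncrna or (lnc_ids[0] if lnc_ids else "")

    kd: Dict[str, Tuple[str, float]] = {}
    if target:
        kd[target] = ("down", config.knockdown_log2fc)

    # triads: the target lncRNA sponges n distinct miRNAs, each repressing
    # a distinct validated mRNA; avoid mRNAs already used as antisense partners
    anti_mrnas = {g for _, g, _ in truth.antisense_pairs}
    triad_mrna_pool = [g for g in mrna_ids if g not in anti_mrnas] or mrna_ids
    for k in range(config.n_planted_triads):
        mir = mir_ids[k]
        gene = triad_mrna_pool[k % len(triad_mrna_pool)]
        truth.triads.add((target, mir, gene))
        truth.validated_mrnas[gene] = "down"
        kd[mir] = ("up", config.triad_log2fc)
        kd[gene] = ("down", config.triad_log2fc)
    truth.dominant_genes = set(truth.validated_mrnas)

    # antisense partners are co-regulated with the target (the pairing stage
    # needs both ends DE); lncRNA side down, mRNA side random sign
    for lid, gid, _ in sorted(truth.antisense_pairs):
        if lid not in kd:
            kd[lid] = ("down", config.planted_log2fc)
        if gid not in kd:
            sign = "up" if rng.random() < 0.5 else "down"
            kd[gid] = (sign, config.planted_log2fc)

    # generic planted DE features fill up to n_planted_de
    pool = [f for f in mrna_ids + lnc_ids if f not in kd]
    n_generic = max(0, config.n_planted_de - len(kd))
    for f in rng.permutation(pool)[:n_generic]:
        sign = "up" if rng.random() < 0.5 else "down"
        kd[str(f)] = (sign, config.planted_log2fc)

    for f, (d, _) in kd.items():
        truth.de_features.add((f, d, KNOCKDOWN_CONTRAST))

    # nonspecific effects: disjoint from triad members and the target, but
    # overlapping `nonspecific_overlap` planted features by design
    protected = {target} | {m for _, m, _ in truth.triads} | {
        g for _, _, g in truth.triads
    }
    all_feats = mrna_ids + lnc_ids + mir_ids
    n_ns = int(round(config.nonspecific_fraction * len(all_feats)))
    ns: Dict[str, Tuple[str, float]] = {}
    overlap_pool = [f for f in sorted(kd) if f not in protected]
    for f in list(rng.permutation(overlap_pool))[: config.nonspecific_overlap]:
        ns[str(f)] = (kd[str(f)][0], config.planted_log2fc)
    ns_pool = [f for f in all_feats if f not in kd and f not in protected]
    for f in rng.permutation(ns_pool)[: max(0, n_ns - len(ns))]:
        sign = "up" if rng.random() < 0.5 else "down"
        ns[str(f)] = (sign, config.planted_log2fc)
    for f, (d, _) in ns.items():
        truth.de_features.add((f, d, NONSPECIFIC_CONTRAST))
    return kd, ns


def simulate_counts(
    annotation: AnnotationSet,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts for the five samples with planted effects."""
    if len(annotation) == 0:
        raise SimulationError("annotation is empty")
    if config.dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    truth = truth if truth is not None else GroundTruth()
    if not truth.target_lncrna:
        lnc = annotation.ids("lncRNA")
        truth.target_lncrna = lnc[0] if lnc else ""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    features = annotation.ids()
    base = rng.lognormal(np.log(config.baseline_mean), config.baseline_sigma, len(features))
    base_by_feat = dict(zip(features, base))

    kd, ns = _plan_effects(annotation, config, truth, rng)

    cols = {}
    for sample in SAMPLES:
        mean = np.array([base_by_feat[f] for f in features])
        if sample in KD_SAMPLES:
            eff = kd
        elif sample in CTRL_SAMPLES:
            eff = ns
        else:
            eff = {}
        for i, f in enumerate(features):
            if f in eff:
                d, lfc = eff[f]
                mean[i] *= 2.0 ** (lfc if d == "up" else -lfc)
        cols[sample] = _nb_draw(rng, mean, config.dispersion)

    counts = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    biotype = pd.Series(
        {f: annotation[f].biotype for f in features}, name="biotype"
    ).reindex(features)
    return ExpressionMatrix(counts=counts, biotype=biotype), truth


# ---------------------------------------------------------------------------
# PPI

def simulate_ppi(
    annotation: AnnotationSet, config: SimulationConfig, m: int = 2
) -> List[Tuple[str, str]]:
    """Scale-free PPI over mRNA-product nodes plus extra proteins.

    Preferential attachment (Barabasi-Albert, ``m`` edges per new node)
    gives a connected simple graph with hubs, matching what the
    first-neighbor and PageRank stages assume about real interactomes.
    """
    nodes = annotation.ids("mRNA") + [
        f"P{i:03d}" for i in range(config.n_protein_extra)
    ]
    n = len(nodes)
    if n < 2:
        raise SimulationError("PPI needs at least 2 nodes")
    m = min(m, n - 1)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    # deterministic attachment order decoupled from annotation order
    order = [nodes[i] for i in rng.permutation(n)]
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    relabel = {i: order[i] for i in range(n)}
    edges = sorted(
        tuple(sorted((relabel[a], relabel[b]))) for a, b in g.edges()
    )
    return edges


# ---------------------------------------------------------------------------
# sequences

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def _scrub_collisions(
    seq: str,
    cores: Dict[str, str],
    protected: Sequence[Tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> str:
    """Remove chance occurrences of any miRNA 6mer core outside protected
    windows by resampling one base of each offending hexamer."""
    s = list(seq)
    for _ in range(max_rounds):
        dirty = False
        text = "".join(s)
        for core in set(cores.values()):
            j = text.find(core)
            while j != -1:
                if not any(ps <= j < pe or ps < j + 6 <= pe for ps, pe in protected):
                    k = j + int(rng.integers(0, 6))
                    choices = [b for b in "ACGT" if b != s[k]]
                    s[k] = choices[int(rng.integers(0, 3))]
                    dirty = True
                j = text.find(core, j + 1)
        if not dirty:
            return "".join(s)
    raise SimulationError("could not scrub chance seed matches")


def simulate_sequences(
    annotation: AnnotationSet,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, str], GroundTruth]:
    """miRNA, 3'UTR and lncRNA sequences with planted 8mer seed sites.

    For every planted triad (lncRNA, miRNA, mRNA) an 8mer site for the
    miRNA is inserted into both the mRNA 3'UTR and the sponge lncRNA
    transcript; insertion positions are recorded in the truth.  With
    ``screen_seed_collisions`` (default) all chance 6mer-core occurrences are
    scrubbed first, so seed evidence equals the planted set exactly.
    """
    truth = truth if truth is not None else GroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    mir_ids = annotation.ids("miRNA")
    mrna_ids = annotation.ids("mRNA")
    lnc_ids = annotation.ids("lncRNA")

    mirna_seqs = {m: _random_seq(rng, 21, "ACGU") for m in mir_ids}
    cores = {m: _revcomp(_normalize(s, "miRNA")[1:7]) for m, s in mirna_seqs.items()}

    site_len = 8
    if config.utr_length < site_len + 2 or config.lnc_transcript_length < site_len + 2:
        raise SimulationError("sequence too short to host a seed site")

    utr_seqs = {g: _random_seq(rng, config.utr_length) for g in mrna_ids}
    lnc_seqs = {l: _random_seq(rng, config.lnc_transcript_length) for l in lnc_ids}

    triads = sorted(truth.triads)
    sites_by_target: Dict[str, List[Tuple[str, int]]] = {}
    for i, (lnc, mir, gene) in enumerate(triads):
        gpos = 20 + (i % 3) * (site_len + 12)
        lpos = 20 + i * (site_len + 12)
        sites_by_target.setdefault(gene, []).append((mir, gpos))
        sites_by_target.setdefault(lnc, []).append((mir, lpos))

    def plant(seqs: Dict[str, str]) -> None:
        for tid in sorted(seqs):
            planned = sites_by_target.get(tid, [])
            protected = []
            s = seqs[tid]
            for mir, pos in planned:
                if pos + site_len > len(s):
                    raise SimulationError(
                        f"sequence {tid} too short to host a site at {pos}"
                    )
                site = _revcomp(_normalize(mirna_seqs[mir], "miRNA")[1:8]) + "A"
                s = s[:pos] + site + s[pos + site_len:]
                protected.append((pos, pos + site_len))
                truth.planted_sites[(mir, tid)] = pos
            if config.screen_seed_collisions:
                s = _scrub_collisions(s, cores, protected, rng)
            seqs[tid] = s

    plant(utr_seqs)
    plant(lnc_seqs)
    return mirna_seqs, utr_seqs, lnc_seqs, truth


# ---------------------------------------------------------------------------
# gene sets

def simulate_gene_sets(
    annotation: AnnotationSet,
    config: SimulationConfig,
    truth: GroundTruth,
    n_random_terms: int = 8,
    term_size: int = 10,
) -> Dict[str, List[str]]:
    """GMT-style gene sets over the mRNA/protein universe.

    One planted pathway collects the triad target genes and antisense mRNA
    partners (so genuinely screened genes can be enriched); the remaining
    terms are random draws from the same universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    universe = annotation.ids("mRNA") + [
        f"P{i:03d}" for i in range(config.n_protein_extra)
    ]
    planted = sorted(
        set(truth.validated_mrnas) | {g for _, g, _ in truth.antisense_pairs}
    )
    sets: Dict[str, List[str]] = {}
    if planted:
        sets["PLANTED_PATHWAY"] = planted
    for i in range(n_random_terms):
        members = sorted(
            str(x) for x in rng.choice(universe, size=min(term_size, len(universe)), replace=False)
        )
        sets[f"RANDOM_TERM_{i:02d}"] = members
    return sets


# ---------------------------------------------------------------------------
# orchestration

def simulate_all(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset with one shared seed."""
    config = config or SimulationConfig()
    annotation, truth = simulate_annotation(config)
    counts, truth = simulate_counts(annotation, config, truth)
    ppi = simulate_ppi(annotation, config)
    mirna_seqs, utr_seqs, lnc_seqs, truth = simulate_sequences(
        annotation, config, truth
    )
    gene_sets = simulate_gene_sets(annotation, config, truth)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        counts=counts,
        ppi=ppi,
        mirna_sequences=mirna_seqs,
        utr_sequences=utr_seqs,
        lncrna_sequences=lnc_seqs,
        gene_sets=gene_sets,
        truth=truth,
    )
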