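"""Set algebra of the specificity screen.

The knockdown profile is the direction-consistent intersection of the two
targeted-knockdown contrasts; the nonspecific profile is the union of the two
control contrasts; control overlap is then removed from the knockdown profile
by feature id.  Directions disagree between the two control contrasts for
some features; those members are kept with direction ``"conflict"`` because
the control set's only role is removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Union

from .diffexp import DEProfile

Direction = str  # "up" | "down" | "conflict"


@dataclass
class FeatureSet:
    """A labelled set of (feature_id -> direction) memberships."""

    label: str
    members: Dict[str, Direction] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.members

    def ids(self) -> set:
        return set(self.members)

    def with_direction(self, direction: Direction) -> "FeatureSet":
        return FeatureSet(
            label=f"{self.label}[{direction}]",
            members={f: d for f, d in self.members.items() if d == direction},
        )


ProfileLike = Union[DEProfile, FeatureSet]


def as_feature_set(profile: ProfileLike, biotype: str | None = None, label: str | None = None) -> FeatureSet:
    """Coerce a DEProfile (optionally restricted to one biotype) to a FeatureSet."""
    if isinstance(profile, FeatureSet):
        return profile
    table = profile.features(biotype)
    name = label or f"{profile.contrast[0]}-vs-{profile.contrast[1]}"
    return FeatureSet(label=name, members=dict(zip(table.index, table["direction"])))


def intersect_consistent(p1: ProfileLike, p2: ProfileLike, biotype: str | None = None) -> FeatureSet:
    """Features significant in BOTH profiles with the SAME direction."""
    a = as_feature_set(p1, biotype)
    b = as_feature_set(p2, biotype)
    members = {
        f: d for f, d in a.members.items() if b.members.get(f) == d and d != "conflict"
    }
    return FeatureSet(label=f"({a.label} & {b.label})", members=members)


def union_profiles(p3: ProfileLike, p4: ProfileLike, biotype: str | None = None) -> FeatureSet:
    """Features significant in EITHER profile; direction conflicts flagged."""
    a = as_feature_set(p3, biotype)
    b = as_feature_set(p4, biotype)
    members = dict(a.members)
    for f, d in b.members.items():
        if f in members and members[f] != d:
            members[f] = "conflict"
        else:
            members[f] = d
    return FeatureSet(label=f"({a.label} | {b.label})", members=members)


def subtract_overlap(study: FeatureSet, control: FeatureSet) -> FeatureSet:
    """Study members whose feature_id does not appear in control.

    Matching is by id only: a control hit in either direction is treated as
    nonspecific noise.
    """
    members = {f: d for f, d in study.members.items() if f not in control.members}
    return FeatureSet(label=f"({study.label} - {control.label})", members=members)


def venn_summary(a: FeatureSet, b: FeatureSet) -> Dict[str, int]:
    """Region cardinalities of the two-set Venn diagram (by feature id)."""
    ia, ib = a.ids(), b.ids()
    return {
        "only_a": len(ia - ib),
        "only_b": len(ib - ia),
        "both": len(ia & ib),
        "union": len(ia | ib),
    }
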