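"""Candidate indicator (surrogate) groups.

Nine groups are built per region: one per taxonomic order large enough
to stand alone, a pooled "species-poor orders" group (orders with fewer
than 17 species), threatened species, endemic species, and
restricted-range species (the 10% of species with the fewest occupied
cells, ties at the cutoff included).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .assemblage import Assemblage, PresenceAbsence

__all__ = [
    "EmptyGroupError",
    "IndicatorGroup",
    "GroupSet",
    "restricted_range_group",
    "species_poor_orders_group",
    "build_all_groups",
    "RESTRICTED_RANGE_FRACTION",
    "SPECIES_POOR_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Fraction of species (smallest occupancy first) forming the
#: restricted-range group.
RESTRICTED_RANGE_FRACTION = 0.10
#: Orders with strictly fewer species than this pool into one group.
SPECIES_POOR_THRESHOLD = 17

RESTRICTED_RANGE = "restricted_range"
SPECIES_POOR = "species_poor_orders"
THREATENED = "threatened"
ENDEMIC = "endemic"


class EmptyGroupError(ValueError):
    """Raised when a group definition selects no species."""


@dataclass(frozen=True)
class IndicatorGroup:
    """A named species subset playing the surrogate role."""

    name: str
    members: frozenset[str]
    kind: str  # taxonomic | threatened | endemic | restricted_range | species_poor_orders

    def __post_init__(self):
        if not self.members:
            raise EmptyGroupError(f"group {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GroupSet:
    """The indicator groups of one region, tied to its assemblage."""

    assemblage: Assemblage
    groups: list[IndicatorGroup]

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise ValueError("group names must be unique")
        species = set(self.assemblage.matrix.species)
        md = self.assemblage.metadata
        for g in self.groups:
            stray = g.members - species
            if stray:
                raise ValueError(f"group {g.name!r} has unknown species {sorted(stray)[0]!r}")
            if g.kind == "taxonomic":
                orders = set(md.loc[list(g.members), "order"])
                if orders != {g.name}:
                    raise ValueError(f"taxonomic group {g.name!r} mixes orders {sorted(orders)}")

    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def __getitem__(self, name: str) -> IndicatorGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (group, species_id) membership table."""
        rows = [(g.name, s) for g in self.groups for s in sorted(g.members)]
        return pd.DataFrame(rows, columns=["group", "species_id"])


def restricted_range_group(
    matrix: PresenceAbsence, fraction: float = RESTRICTED_RANGE_FRACTION
) -> IndicatorGroup:
    """Species in the smallest-occupancy ``fraction``, ties included.

    Ranks species by occupied-cell count ascending, takes
    ``k = ceil(fraction * S)`` species, and adds every species tied with
    the k-th occupancy value, so the group is well defined regardless of
    row order.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    occ = matrix.occupancy()
    if len(occ) < 1:
        raise ValueError("matrix has no species")
    k = math.ceil(fraction * len(occ))
    cutoff = occ.sort_values(kind="stable").iloc[k - 1]
    members = frozenset(occ.index[occ <= cutoff])
    return IndicatorGroup(RESTRICTED_RANGE, members, "restricted_range")


def species_poor_orders_group(
    metadata: pd.DataFrame, threshold: int = SPECIES_POOR_THRESHOLD
) -> IndicatorGroup:
    """Union of all orders with strictly fewer than ``threshold`` species."""
    sizes = metadata["order"].value_counts()
    poor = sizes.index[sizes < threshold]
    members = frozenset(metadata.index[metadata["order"].isin(poor)])
    if not members:
        raise EmptyGroupError(
            f"no order has fewer than {threshold} species; species-poor group is empty"
        )
    return IndicatorGroup(SPECIES_POOR, members, "species_poor_orders")


def build_all_groups(
    assemblage: Assemblage,
    fraction: float = RESTRICTED_RANGE_FRACTION,
    poor_threshold: int = SPECIES_POOR_THRESHOLD,
) -> GroupSet:
    """Construct the candidate indicator groups for one region.

    Orders with at least ``poor_threshold`` species each become a
    taxonomic group named after the order (in metadata appearance
    order); the rest pool into the species-poor group. Flag-based and
    restricted-range groups follow. Any group empty in this region is
    skipped with a logged warning rather than failing the region.
    """
    md = assemblage.metadata
    groups: list[IndicatorGroup] = []

    sizes = md["order"].value_counts()
    seen: list[str] = []
    for order in md["order"]:
        if order not in seen:
            seen.append(order)
    for order in seen:
        if sizes[order] >= poor_threshold:
            members = frozenset(md.index[md["order"] == order])
            groups.append(IndicatorGroup(order, members, "taxonomic"))

    try:
        groups.append(species_poor_orders_group(md, poor_threshold))
    except EmptyGroupError as exc:
        logger.warning("%s: skipping group: %s", assemblage.region, exc)

    for flag, kind in ((THREATENED, "threatened"), (ENDEMIC, "endemic")):
        members = frozenset(md.index[md[flag]])
        if members:
            groups.append(IndicatorGroup(flag, members, kind))
        else:
            logger.warning("%s: skipping empty group %r", assemblage.region, flag)

    groups.append(restricted_range_group(assemblage.matrix, fraction))
    return GroupSet(assemblage=assemblage, groups=groups)
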