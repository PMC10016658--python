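"""The 30-region canine parcellation atlas.

The parcellation covers 14 bilateral cortical/subcortical regions (labels
1-14 left, 15-28 right, in the same order) plus two midline structures,
mesencephalon (29) and diencephalon (30).  The a-priori anxiety circuit is
{amygdala, frontal lobe, hippocampus, mesencephalon, thalamus}; the
cerebellar vermis serves as the negative-control region in nodal
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Region",
    "Atlas",
    "canine_atlas",
    "CIRCUIT_REGIONS",
    "CONTROL_REGION",
]

#: Anxiety-circuit regions (region base names, hemisphere-agnostic).
CIRCUIT_REGIONS: tuple[str, ...] = (
    "amygdala",
    "frontal lobe",
    "hippocampus",
    "mesencephalon",
    "thalamus",
)

#: Negative-control region for nodal comparisons.
CONTROL_REGION: str = "vermis"

# Bilateral base regions in label order (label i = left, label i+14 = right).
_BILATERAL = (
    "temporal lobe",
    "parietal lobe",
    "occipital lobe",
    "frontal lobe",
    "anterior cingulate gyrus",
    "posterior cingulate gyrus",
    "hippocampus",
    "thalamus",
    "caudate nucleus",
    "piriform lobe",
    "insular cortex",
    "amygdala",
    "cerebral hemisphere",
    "vermis",
)

_MIDLINE = ("mesencephalon", "diencephalon")


@dataclass(frozen=True)
class Region:
    """One atlas entry.

    ``label`` is the 1-based atlas label; ``base`` the hemisphere-agnostic
    region name; ``hemisphere`` one of ``"L"``, ``"R"``, ``"midline"``.
    """

    label: int
    base: str
    hemisphere: str

    @property
    def name(self) -> str:
        if self.hemisphere == "midline":
            return self.base.capitalize()
        return f"{self.base.capitalize()} {self.hemisphere}"


@dataclass(frozen=True)
class Atlas:
    """Ordered region list with hemisphere bookkeeping.

    Node indices used throughout the package are 0-based positions into
    ``regions`` (label - 1).
    """

    regions: tuple[Region, ...]
    circuit_regions: tuple[str, ...] = CIRCUIT_REGIONS
    control_region: str = CONTROL_REGION
    _base_index: dict = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.regions) != len({r.label for r in self.regions}):
            raise ValueError("duplicate atlas labels")
        idx: dict[str, list[int]] = {}
        for pos, region in enumerate(self.regions):
            if region.label != pos + 1:
                raise ValueError("atlas labels must be consecutive starting at 1")
            idx.setdefault(region.base, []).append(pos)
        for base, nodes in idx.items():
            hemis = {self.regions[i].hemisphere for i in nodes}
            if hemis == {"midline"} and len(nodes) != 1:
                raise ValueError(f"midline region {base!r} duplicated")
            if "midline" not in hemis and hemis != {"L", "R"}:
                raise ValueError(f"bilateral region {base!r} missing a hemisphere")
        object.__setattr__(self, "_base_index", idx)
        for base in (*self.circuit_regions, self.control_region):
            if base not in idx:
                raise ValueError(f"region {base!r} not in atlas")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        """Full per-node names, e.g. ``'Amygdala L'``."""
        return [r.name for r in self.regions]

    @property
    def base_names(self) -> list[str]:
        """Hemisphere-agnostic region names, bilateral first, atlas order."""
        seen: list[str] = []
        for r in self.regions:
            if r.base not in seen:
                seen.append(r.base)
        return seen

    @property
    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """(left, right) 0-based node index pairs for the bilateral regions."""
        pairs = []
        for base, nodes in self._base_index.items():
            if len(nodes) == 2:
                left = next(i for i in nodes if self.regions[i].hemisphere == "L")
                right = next(i for i in nodes if self.regions[i].hemisphere == "R")
                pairs.append((left, right))
        return sorted(pairs)

    def nodes_of(self, base: str) -> list[int]:
        """0-based node indices belonging to a base region."""
        base = base.strip().lower()
        try:
            return list(self._base_index[base])
        except KeyError:
            raise KeyError(f"unknown atlas region: {base!r}") from None

    def is_bilateral(self, base: str) -> bool:
        return len(self.nodes_of(base)) == 2

    def spanning_node_pairs(
        self, region_a: str, region_b: str
    ) -> list[tuple[int, int]]:
        """All node pairs linking two base regions.

        For two distinct bilateral regions this yields the 4 intra- and
        interhemispheric pairs; bilateral x midline yields 2; midline x
        midline yields 1.  Passing the same bilateral region twice yields
        its single homotopic (L-R) pair.
        """
        a, b = region_a.strip().lower(), region_b.strip().lower()
        if a == b:
            nodes = self.nodes_of(a)
            if len(nodes) != 2:
                raise ValueError(f"{a!r} is midline: it has no homotopic pair")
            return [tuple(sorted(nodes))]
        return [
            (min(i, j), max(i, j))
            for i in self.nodes_of(a)
            for j in self.nodes_of(b)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.regions],
                "region": self.names,
                "hemisphere": [r.hemisphere for r in self.regions],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Atlas":
        """Build an atlas from a table with label/region/hemisphere columns."""
        regions = []
        for _, row in df.sort_values("label").iterrows():
            hemi = str(row["hemisphere"])
            name = str(row["region"]).strip().lower()
            if hemi in ("L", "R") and name.endswith(f" {hemi.lower()}"):
                name = name[:-2].strip()
            regions.append(Region(int(row["label"]), name, hemi))
        return cls(tuple(regions))


def canine_atlas() -> Atlas:
    """The study's 30-region atlas (labels 1-30)."""
    regions = [
        Region(i + 1, base, "L") for i, base in enumerate(_BILATERAL)
    ] + [
        Region(i + 15, base, "R") for i, base in enumerate(_BILATERAL)
    ] + [
        Region(i + 29, base, "midline") for i, base in enumerate(_MIDLINE)
    ]
    return Atlas(tuple(regions))
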