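"""Region catalog: syntax-related cortical regions, their networks, and pair partitions.

The catalog holds 25 regions grouped into four connectivity networks
(I-IV).  Fourteen of them are the previously established "core" regions
of networks I-III; the remaining eleven ("additional") were localized by
a harder-minus-easier syntactic contrast, five of which extend networks
I-III while six form network IV.  Every unordered region pair is either
*within* one network or *between* two networks ("cross-talk"); the
partition drives all downstream similarity and flagging statistics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

NETWORKS = ("I", "II", "III", "IV")
SIDES = ("left", "right", "medial")

_SIDE_ALIASES = {
    "l": "left", "left": "left",
    "r": "right", "right": "right",
    "m": "medial", "medial": "medial",
}

#: plausible MNI bounds (mm): |x|,|y| <= 90, |z| <= 110
_MNI_BOUNDS = (90.0, 90.0, 110.0)


class CatalogError(ValueError):
    """Raised for malformed region tables or invalid catalog queries."""


@dataclass(frozen=True)
class RegionSpec:
    """One node: an anatomical region with an MNI peak coordinate.

    Slash-composite labels (e.g. ``L_F3op/F3t``) are single atomic
    nodes; homotopic duplicates are disambiguated by the side prefix.
    """

    name: str
    side: str
    network: str
    center_mm: tuple[float, float, float]
    additional: bool = False
    brodmann: str = ""

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise CatalogError(
                f"region {self.name!r}: unknown network {self.network!r} "
                f"(expected one of {NETWORKS})"
            )
        if self.side not in SIDES:
            raise CatalogError(
                f"region {self.name!r}: unknown side {self.side!r} "
                f"(expected one of {SIDES})"
            )
        if len(self.center_mm) != 3:
            raise CatalogError(f"region {self.name!r}: coordinate must be a triple")
        for axis, (value, bound) in enumerate(zip(self.center_mm, _MNI_BOUNDS)):
            if not abs(float(value)) <= bound:
                raise CatalogError(
                    f"region {self.name!r}: coordinate axis {axis} value {value} "
                    f"outside plausible MNI bounds (+/-{bound} mm)"
                )


@dataclass(frozen=True)
class PairLabel:
    """An unordered region pair with its partition label.

    ``networks`` is ``(k,)`` for a within-network pair and ``(k, l)``
    with k before l in network order for a between-network pair.
    """

    region_a: str
    region_b: str
    kind: str  # "within" | "between"
    networks: tuple[str, ...]

    @property
    def label(self) -> str:
        if self.kind == "within":
            return f"within({self.networks[0]})"
        return f"between({self.networks[0]},{self.networks[1]})"


@dataclass(frozen=True)
class PairClassification:
    """Every unordered pair of catalog regions, labeled within/between."""

    pairs: tuple[PairLabel, ...]
    region_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[PairLabel]:
        return iter(self.pairs)

    def subset(self, kind: str, network: str | None = None) -> tuple[PairLabel, ...]:
        """Select pairs by kind ("within" | "between" | "all").

        With ``network`` given, within-pairs must lie in that network and
        between-pairs must have it as one endpoint network.
        """
        if kind not in ("within", "between", "all"):
            raise CatalogError(f"unknown pair subset kind {kind!r}")
        selected = self.pairs if kind == "all" else tuple(
            p for p in self.pairs if p.kind == kind
        )
        if network is not None:
            if network not in NETWORKS:
                raise CatalogError(f"unknown network {network!r}")
            selected = tuple(p for p in selected if network in p.networks)
        return selected

    @property
    def n_within(self) -> int:
        return sum(1 for p in self.pairs if p.kind == "within")

    @property
    def n_between(self) -> int:
        return sum(1 for p in self.pairs if p.kind == "between")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_a": [p.region_a for p in self.pairs],
                "region_b": [p.region_b for p in self.pairs],
                "kind": [p.kind for p in self.pairs],
                "label": [p.label for p in self.pairs],
            }
        )


@dataclass(frozen=True)
class RegionCatalog:
    """Ordered collection of regions with a name-uniqueness index."""

    regions: tuple[RegionSpec, ...]
    _index: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        for i, region in enumerate(self.regions):
            if region.name in index:
                raise CatalogError(f"duplicate region name {region.name!r}")
            index[region.name] = i
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[RegionSpec]:
        return iter(self.regions)

    def __getitem__(self, name: str) -> RegionSpec:
        try:
            return self.regions[self._index[name]]
        except KeyError:
            raise CatalogError(f"unknown region name {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise CatalogError(f"unknown region name {name!r}") from None

    def restrict(self, names: Sequence[str]) -> "RegionCatalog":
        """Sub-catalog of the named regions, kept in catalog order."""
        for n in names:
            if n not in self._index:
                raise CatalogError(f"unknown region name {n!r}")
        wanted = set(names)
        return RegionCatalog(tuple(r for r in self.regions if r.name in wanted))

    def core(self) -> "RegionCatalog":
        """The previously established regions (additional=False)."""
        return RegionCatalog(tuple(r for r in self.regions if not r.additional))

    def additional_regions(self) -> "RegionCatalog":
        return RegionCatalog(tuple(r for r in self.regions if r.additional))


def load_region_table(path) -> RegionCatalog:
    """Read a region table TSV into a :class:`RegionCatalog`.

    Columns: ``name side network x y z additional`` (plus optional
    ``brodmann``); coordinates in MNI mm; file row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["name", "side", "network", "x", "y", "z", "additional"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"region table missing columns {missing}")
    regions = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            center = (float(row.x), float(row.y), float(row.z))
        except ValueError as exc:
            raise CatalogError(
                f"row {row_no} ({row.name!r}): malformed coordinate "
                f"({row.x!r}, {row.y!r}, {row.z!r})"
            ) from exc
        side = _SIDE_ALIASES.get(str(row.side).strip().lower())
        if side is None:
            raise CatalogError(f"row {row_no} ({row.name!r}): unknown side {row.side!r}")
        add_raw = str(row.additional).strip().lower()
        if add_raw in ("1", "true", "yes"):
            additional = True
        elif add_raw in ("0", "false", "no"):
            additional = False
        else:
            raise CatalogError(
                f"row {row_no} ({row.name!r}): malformed additional flag {row.additional!r}"
            )
        brodmann = str(getattr(row, "brodmann", "") or "")
        regions.append(
            RegionSpec(
                name=str(row.name),
                side=side,
                network=str(row.network).strip(),
                center_mm=center,
                additional=additional,
                brodmann=brodmann,
            )
        )
    return RegionCatalog(tuple(regions))


def write_region_table(catalog: RegionCatalog, path) -> None:
    """Write a catalog back to TSV; round-trips with :func:`load_region_table`."""
    side_out = {"left": "L", "right": "R", "medial": "M"}
    df = pd.DataFrame(
        {
            "name": [r.name for r in catalog],
            "side": [side_out[r.side] for r in catalog],
            "network": [r.network for r in catalog],
            "x": [_fmt_coord(r.center_mm[0]) for r in catalog],
            "y": [_fmt_coord(r.center_mm[1]) for r in catalog],
            "z": [_fmt_coord(r.center_mm[2]) for r in catalog],
            "additional": [int(r.additional) for r in catalog],
            "brodmann": [r.brodmann for r in catalog],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _fmt_coord(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def default_catalog() -> RegionCatalog:
    """The packaged 25-region catalog (networks I-IV)."""
    ref = importlib.resources.files("syntaxconn.data") / "regions_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_region_table(path)


def classify_pairs(
    catalog: RegionCatalog, subset: Iterable[str] | None = None
) -> PairClassification:
    """Label every unordered region pair within-network(k) or between(k,l).

    ``subset`` optionally restricts to the named regions; the pair list
    is ordered lexicographically by catalog order regardless of the
    order names appear in ``subset``.
    """
    cat = catalog if subset is None else catalog.restrict(list(subset))
    pairs = []
    for i, a in enumerate(cat.regions):
        for b in cat.regions[i + 1:]:
            if a.network == b.network:
                pairs.append(PairLabel(a.name, b.name, "within", (a.network,)))
            else:
                k, l = sorted((a.network, b.network), key=NETWORKS.index)
                pairs.append(PairLabel(a.name, b.name, "between", (k, l)))
    return PairClassification(tuple(pairs), cat.names)


def network_sizes(catalog: RegionCatalog) -> dict[str, int]:
    """Region count per network, in canonical network order (I < II < III < IV)."""
    counts = {n: 0 for n in NETWORKS}
    for region in catalog:
        counts[region.network] += 1
    return {n: c for n, c in counts.items() if c > 0}
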