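"""Architecture genomes for evolutionary U-Net search.

A genome encodes the four evolved hyperparameters of an encoder--decoder
segmentation network: the dropout rate ``p_d`` (in [0, 0.5]), the per-level
filter counts ``F = (f_1, ..., f_d)`` ordered from the shallowest encoder
level down, the depth ``d`` (number of encoder levels), and a boolean skip
flag ``u_s`` selecting whether decoder levels concatenate the matching
encoder feature maps.

The module also carries the catalog of legal filter configurations used to
seed initial populations, the bound system used for clipping, and a JSON
serialization dialect used for checkpoints and reproducible tie-breaking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Genome",
    "GenomeBounds",
    "FilterCatalog",
    "GenomeFormatError",
    "default_catalog",
    "validate_genome",
    "sample_initial_population",
    "clip_to_bounds",
    "serialize_genome",
    "deserialize_genome",
    "snap_to_pow2",
]


class GenomeFormatError(ValueError):
    """Raised when a genome record cannot be parsed."""


@dataclass(frozen=True)
class Genome:
    """One candidate architecture.

    Parameters
    ----------
    dropout_rate : float
        Dropout probability applied once per encoder/decoder level, in
        ``[0, 0.5]``.
    filters : tuple of int
        Filter counts per encoder level, shallowest first; the decoder
        mirrors them.
    depth : int
        Number of encoder levels; must equal ``len(filters)`` for a valid
        genome.
    use_skip : bool
        Whether decoder levels concatenate the matching encoder features.
    """

    dropout_rate: float
    filters: tuple[int, ...]
    depth: int
    use_skip: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "dropout_rate", float(self.dropout_rate))
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        object.__setattr__(self, "depth", int(self.depth))
        object.__setattr__(self, "use_skip", bool(self.use_skip))


@dataclass(frozen=True)
class GenomeBounds:
    """Legal parameter ranges used by validation and clipping."""

    dropout_min: float = 0.0
    dropout_max: float = 0.5
    f_min: int = 8
    f_max: int = 1024
    depth_set: frozenset[int] = frozenset({3, 4, 5, 6})

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_set", frozenset(int(d) for d in self.depth_set))
        if not self.dropout_min < self.dropout_max:
            raise ValueError("dropout_min must be < dropout_max")
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be < f_max")
        if not self.depth_set:
            raise ValueError("depth_set must be nonempty")


# Catalog of filter configurations explored per depth.  The depth-3 row has
# seven entries; depths 4/5/6 have six/five/five.
_DEFAULT_CATALOG_ENTRIES: dict[int, tuple[tuple[int, ...], ...]] = {
    3: (
        (8, 16, 128),
        (8, 32, 128),
        (16, 32, 128),
        (8, 64, 256),
        (64, 128, 256),
        (16, 32, 64),
        (32, 64, 128),
    ),
    4: (
        (16, 32, 64, 128),
        (64, 128, 256, 512),
        (8, 32, 128, 256),
        (8, 64, 128, 512),
        (16, 64, 128, 256),
        (32, 64, 128, 256),
    ),
    5: (
        (16, 32, 64, 128, 256),
        (32, 64, 128, 256, 512),
        (8, 32, 128, 256, 512),
        (8, 64, 256, 512, 1024),
        (64, 128, 256, 512, 1024),
    ),
    6: (
        (32, 64, 128, 256, 512, 1024),
        (8, 16, 64, 128, 256, 512),
        (16, 32, 64, 128, 256, 512),
        (8, 32, 128, 256, 512, 1024),
        (16, 32, 128, 256, 512, 1024),
    ),
}


@dataclass(frozen=True)
class FilterCatalog:
    """Mapping from depth to the legal filter lists for that depth."""

    entries: Mapping[int, tuple[tuple[int, ...], ...]]

    def __post_init__(self) -> None:
        fixed = {
            int(d): tuple(tuple(int(f) for f in row) for row in rows)
            for d, rows in self.entries.items()
        }
        for d, rows in fixed.items():
            for row in rows:
                if len(row) != d:
                    raise ValueError(
                        f"catalog row {list(row)} has length {len(row)}, "
                        f"expected {d} for its depth key"
                    )
        object.__setattr__(self, "entries", fixed)

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    def entries_for(self, depth: int) -> tuple[tuple[int, ...], ...]:
        try:
            return self.entries[int(depth)]
        except KeyError:
            raise KeyError(
                f"depth {depth} is not in the filter catalog "
                f"(known depths: {sorted(self.entries)})"
            ) from None

    def to_yaml(self, path) -> None:
        payload = {int(d): [list(r) for r in rows] for d, rows in self.entries.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FilterCatalog":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, Mapping):
            raise GenomeFormatError("catalog YAML must map depth -> list of filter lists")
        return cls(entries={int(d): tuple(tuple(r) for r in rows) for d, rows in payload.items()})


def default_catalog() -> FilterCatalog:
    """The shipped catalog of filter configurations for depths 3--6."""
    return FilterCatalog(entries=_DEFAULT_CATALOG_ENTRIES)


def validate_genome(g: Genome, bounds: GenomeBounds) -> list[str]:
    """Check a genome against the bound system.

    Returns one human-readable entry per violated invariant; an empty list
    means the genome is legal.  Reports rather than raises so callers can
    aggregate violations.
    """
    violations: list[str] = []
    if len(g.filters) != g.depth:
        violations.append(
            f"filters has length {len(g.filters)} but depth is {g.depth}"
        )
    for i, f in enumerate(g.filters):
        if not bounds.f_min <= f <= bounds.f_max:
            violations.append(
                f"filters[{i}] = {f} outside [{bounds.f_min}, {bounds.f_max}]"
            )
    if not bounds.dropout_min <= g.dropout_rate <= bounds.dropout_max:
        violations.append(
            f"dropout_rate = {g.dropout_rate} outside "
            f"[{bounds.dropout_min}, {bounds.dropout_max}]"
        )
    if g.depth not in bounds.depth_set:
        violations.append(
            f"depth = {g.depth} not in configured depth set {sorted(bounds.depth_set)}"
        )
    return violations


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_initial_population(
    depth: int,
    catalog: FilterCatalog,
    n: int,
    rng,
    bounds: GenomeBounds | None = None,
) -> list[Genome]:
    """Seed a same-depth subpopulation from the filter catalog.

    Filter lists come from the catalog entry for ``depth``.  When ``n`` is at
    least the number of catalog entries, every entry appears at least once
    (a shuffled cycle); below that, entries are drawn without replacement.
    This keeps initial diversity maximal and makes small-scale exhaustive
    searches cover the whole catalog in generation one.  Dropout is uniform
    on the legal range and the skip flag is a fair coin.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    bounds = bounds or GenomeBounds()
    rng = _as_rng(rng)
    rows = catalog.entries_for(depth)
    order: list[tuple[int, ...]] = []
    while len(order) < n:
        idx = rng.permutation(len(rows))
        order.extend(rows[i] for i in idx)
    population = []
    for row in order[:n]:
        population.append(
            Genome(
                dropout_rate=float(rng.uniform(bounds.dropout_min, bounds.dropout_max)),
                filters=row,
                depth=depth,
                use_skip=bool(rng.integers(0, 2)),
            )
        )
    return population


def clip_to_bounds(g: Genome, bounds: GenomeBounds) -> Genome:
    """Project a genome onto the legal box: clamp dropout and every filter.

    Depth and skip flag are left untouched.  Idempotent.
    """
    return Genome(
        dropout_rate=min(max(g.dropout_rate, bounds.dropout_min), bounds.dropout_max),
        filters=tuple(min(max(f, bounds.f_min), bounds.f_max) for f in g.filters),
        depth=g.depth,
        use_skip=g.use_skip,
    )


def snap_to_pow2(value: int, bounds: GenomeBounds) -> int:
    """Round a filter count to the nearest in-bounds power of two."""
    value = max(int(value), 1)
    lo = 2 ** math.floor(math.log2(value))
    hi = lo * 2
    snapped = lo if (value - lo) <= (hi - value) else hi
    return min(max(snapped, bounds.f_min), bounds.f_max)


_FIELDS = ("dropout_rate", "filters", "depth", "use_skip")


def serialize_genome(g: Genome) -> str:
    """One-line JSON record with the four genome fields, key-sorted.

    The text is canonical for a given genome, so it doubles as a stable
    secondary sort key and a cache/checkpoint identity.
    """
    return json.dumps(
        {
            "dropout_rate": g.dropout_rate,
            "filters": list(g.filters),
            "depth": g.depth,
            "use_skip": g.use_skip,
        },
        sort_keys=True,
        separators=(",", ":"),
    )


def deserialize_genome(text: str) -> Genome:
    """Parse a genome record; raises :class:`GenomeFormatError` naming the
    offending field on malformed input."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GenomeFormatError(f"genome record is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise GenomeFormatError("genome record must be a JSON object")
    for name in _FIELDS:
        if name not in payload:
            raise GenomeFormatError(f"genome record missing field '{name}'")
    dropout = payload["dropout_rate"]
    if not isinstance(dropout, (int, float)) or isinstance(dropout, bool):
        raise GenomeFormatError("field 'dropout_rate' must be a number")
    filters = payload["filters"]
    if not isinstance(filters, list) or not all(
        isinstance(f, int) and not isinstance(f, bool) for f in filters
    ):
        raise GenomeFormatError("field 'filters' must be a list of integers")
    depth = payload["depth"]
    if not isinstance(depth, int) or isinstance(depth, bool):
        raise GenomeFormatError("field 'depth' must be an integer")
    use_skip = payload["use_skip"]
    if not isinstance(use_skip, bool):
        raise GenomeFormatError("field 'use_skip' must be a boolean")
    return Genome(
        dropout_rate=float(dropout),
        filters=tuple(filters),
        depth=depth,
        use_skip=use_skip,
    )
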