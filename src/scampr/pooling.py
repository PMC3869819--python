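"""Tri-dimensional pooling designs for mutant-population screens.

A population of mutant lines arrayed on 96-well plates is combined into
column-block, row-pair and plate pools so that every line is present in
exactly three pools (one per dimension).  A variant carried by a single
line then shows up in exactly one pool triple, whose intersection
resolves the carrier to a small set of wells (six in the canonical
4-plate / 12-pool layout).

Designs are data: the canonical layout is registered by name, and
alternative layouts (e.g. per-plate rotations of the colouring) can be
loaded from a JSON config without code changes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))


class DesignError(ValueError):
    """Raised for unknown schemes, bad addresses or inconsistent pool sets."""


@dataclass(frozen=True, order=True)
class LineAddress:
    """A single M2 line: 1-based plate, row letter A-H, column 1-12."""

    plate: int
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.plate < 1:
            raise DesignError(f"plate must be >= 1, got {self.plate}")
        if self.row not in ROWS:
            raise DesignError(f"row must be one of {ROWS}, got {self.row!r}")
        if not 1 <= self.column <= 12:
            raise DesignError(f"column must be in 1..12, got {self.column}")

    @property
    def well(self) -> str:
        return f"{self.row}{self.column}"

    def __str__(self) -> str:  # "plate 4 - E5"
        return f"plate {self.plate} - {self.well}"


@dataclass
class ValidationReport:
    """Outcome of checking a design against its structural invariants."""

    valid: bool
    violations: list[str]
    triples_checked: int
    triples_decoding_to: dict[int, int]  # decoded-set size -> number of triples


@dataclass
class PoolingDesign:
    """Line <-> pool incidence structure for a multi-plate population.

    Attributes
    ----------
    scheme_id : str
        Registered name of the layout.
    n_plates : int
        Number of 96-well plates.
    dimensions : mapping of dimension name -> ordered pool ids
        Each dimension's pools partition the population.
    membership : mapping of pool id -> frozenset of LineAddress
    """

    scheme_id: str
    n_plates: int
    dimensions: dict[str, tuple[int, ...]]
    membership: dict[int, frozenset[LineAddress]]
    _dim_of: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._dim_of = {
            pid: dim for dim, pids in self.dimensions.items() for pid in pids
        }
        missing = set(self._dim_of) - set(self.membership)
        if missing:
            raise DesignError(f"pools without membership: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------
    @property
    def pool_ids(self) -> tuple[int, ...]:
        return tuple(pid for pids in self.dimensions.values() for pid in pids)

    @property
    def lines(self) -> frozenset[LineAddress]:
        out: set[LineAddress] = set()
        for members in self.membership.values():
            out |= members
        return frozenset(out)

    def dimension_of(self, pool_id: int) -> str:
        try:
            return self._dim_of[pool_id]
        except KeyError:
            raise DesignError(f"unknown pool id {pool_id}") from None

    # -- encode / decode -------------------------------------------------
    def pools_for_line(self, address: LineAddress) -> frozenset[int]:
        """The pools containing ``address`` — exactly one per dimension."""
        if address not in self.lines:
            raise DesignError(f"{address} is outside this design")
        hits = frozenset(
            pid for pid, members in self.membership.items() if address in members
        )
        dims = {self.dimension_of(p) for p in hits}
        if len(hits) != len(self.dimensions) or len(dims) != len(self.dimensions):
            raise DesignError(
                f"{address} is in pools {sorted(hits)}; design is inconsistent"
            )
        return hits

    def decode_pools(self, pools: Iterable[int]) -> frozenset[LineAddress]:
        """Intersect pool memberships to the candidate line set.

        A full triple (one pool per dimension) localises a variant to the
        smallest resolvable set; fewer pools return the larger
        intersection so partial evidence can still be reported.
        """
        pool_list = sorted(set(pools))
        if not pool_list:
            raise DesignError("empty pool set")
        seen_dims: dict[str, int] = {}
        for pid in pool_list:
            dim = self.dimension_of(pid)
            if dim in seen_dims:
                raise DesignError(
                    f"pools {seen_dims[dim]} and {pid} are both {dim} pools: "
                    "impossible signature for a single carrier"
                )
            seen_dims[dim] = pid
        result: frozenset[LineAddress] | None = None
        for pid in pool_list:
            members = self.membership[pid]
            result = members if result is None else result & members
        assert result is not None
        if not result:
            raise DesignError(f"pools {pool_list} have an empty intersection")
        return result

    # -- validation ------------------------------------------------------
    def validate(self) -> ValidationReport:
        """Check the structural invariants; violations are reported, not raised."""
        violations: list[str] = []
        lines = self.lines
        expected_pools_per_line = len(self.dimensions)
        for addr in sorted(lines):
            hits = [p for p, m in self.membership.items() if addr in m]
            if len(hits) != expected_pools_per_line:
                violations.append(f"{addr} is in {len(hits)} pools: {sorted(hits)}")
                continue
            dims = {self.dimension_of(p) for p in hits}
            if len(dims) != expected_pools_per_line:
                violations.append(f"{addr} pools {sorted(hits)} repeat a dimension")
        for dim, pids in self.dimensions.items():
            union: set[LineAddress] = set()
            for pid in pids:
                if union & self.membership[pid]:
                    violations.append(f"{dim} pools overlap at pool {pid}")
                union |= self.membership[pid]
            if union != set(lines):
                violations.append(f"{dim} pools do not cover the population")
        sizes = {len(m) for m in self.membership.values()}
        if len(sizes) > 1:
            violations.append(f"unequal pool sizes: {sorted(sizes)}")
        # brute-force every full triple
        size_hist: dict[int, int] = {}
        n_triples = 0
        for combo in itertools.product(*self.dimensions.values()):
            n_triples += 1
            try:
                decoded = self.decode_pools(combo)
                size = len(decoded)
            except DesignError:
                size = 0
            size_hist[size] = size_hist.get(size, 0) + 1
        return ValidationReport(
            valid=not violations,
            violations=violations,
            triples_checked=n_triples,
            triples_decoding_to=size_hist,
        )

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "n_plates": self.n_plates,
            "dimensions": {d: list(p) for d, p in self.dimensions.items()},
            "membership": {
                str(pid): sorted(f"{a.plate}:{a.well}" for a in members)
                for pid, members in self.membership.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PoolingDesign":
        membership = {}
        for pid, wells in payload["membership"].items():
            addrs = set()
            for token in wells:
                plate, well = token.split(":")
                addrs.add(LineAddress(int(plate), well[0], int(well[1:])))
            membership[int(pid)] = frozenset(addrs)
        return cls(
            scheme_id=payload["scheme_id"],
            n_plates=int(payload["n_plates"]),
            dimensions={
                d: tuple(int(p) for p in pids)
                for d, pids in payload["dimensions"].items()
            },
            membership=membership,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PoolingDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# scheme registry
# ---------------------------------------------------------------------------

def _build_canonical384(n_plates: int) -> PoolingDesign:
    """Canonical 4-plate layout: 12 pools of 96 lines.

    Pools 1-4 are column blocks {1-3},{4-6},{7-9},{10-12} across all
    plates, pools 5-8 are row pairs {A,B},{C,D},{E,F},{G,H} across all
    plates, and pools 9-12 are whole plates 1-4.
    """
    if n_plates != 4:
        raise DesignError(
            f"scheme 'canonical384' requires 4 plates, got {n_plates}"
        )
    all_lines = [
        LineAddress(plate, row, col)
        for plate in range(1, 5)
        for row in ROWS
        for col in COLUMNS
    ]
    membership: dict[int, frozenset[LineAddress]] = {}
    for k in range(4):  # column blocks
        cols = {3 * k + 1, 3 * k + 2, 3 * k + 3}
        membership[k + 1] = frozenset(a for a in all_lines if a.column in cols)
    for k in range(4):  # row pairs
        rows = {ROWS[2 * k], ROWS[2 * k + 1]}
        membership[k + 5] = frozenset(a for a in all_lines if a.row in rows)
    for k in range(4):  # plates
        membership[k + 9] = frozenset(a for a in all_lines if a.plate == k + 1)
    return PoolingDesign(
        scheme_id="canonical384",
        n_plates=4,
        dimensions={
            "column": (1, 2, 3, 4),
            "row": (5, 6, 7, 8),
            "plate": (9, 10, 11, 12),
        },
        membership=membership,
    )


_SCHEMES: dict[str, Callable[[int], PoolingDesign]] = {
    "canonical384": _build_canonical384,
}


def register_scheme(scheme_id: str, builder: Callable[[int], PoolingDesign]) -> None:
    """Register a layout builder under ``scheme_id`` (overwrites)."""
    _SCHEMES[scheme_id] = builder


def register_scheme_from_config(path) -> str:
    """Register an explicit-well-list layout from a design JSON file."""
    design = PoolingDesign.from_json(path)

    def _builder(n_plates: int, _design=design) -> PoolingDesign:
        if n_plates != _design.n_plates:
            raise DesignError(
                f"scheme {_design.scheme_id!r} requires {_design.n_plates} plates"
            )
        return _design

    register_scheme(design.scheme_id, _builder)
    return design.scheme_id


def build_design(n_plates: int, scheme_id: str = "canonical384") -> PoolingDesign:
    """Build a registered pooling design for ``n_plates`` plates."""
    if n_plates < 1:
        raise DesignError(f"n_plates must be >= 1, got {n_plates}")
    try:
        builder = _SCHEMES[scheme_id]
    except KeyError:
        raise DesignError(
            f"unknown scheme {scheme_id!r}; registered: {sorted(_SCHEMES)}"
        ) from None
    return builder(n_plates)


def pools_for_line(design: PoolingDesign, address: LineAddress) -> frozenset[int]:
    return design.pools_for_line(address)


def decode_pools(design: PoolingDesign, pools: Iterable[int]) -> frozenset[LineAddress]:
    return design.decode_pools(pools)


def validate_design(design: PoolingDesign) -> ValidationReport:
    return design.validate()
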