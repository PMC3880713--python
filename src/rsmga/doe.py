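"""Factor spaces, coded/natural unit conversion and central-composite designs.

A :class:`FactorSpace` holds named continuous factors with [low, high] bounds
in natural units.  Coded units rescale each factor so that its design range
maps onto [-1, +1] with the centre at 0:

    coded = (natural - center) / half_range,   center = (low+high)/2,
                                               half_range = (high-low)/2.

All model fitting downstream happens in coded units; the coding map is exact
and invertible, so results can always be reported back in natural units.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorSpace",
    "DesignTable",
    "ReplicateGrouping",
    "face_centered_ccd",
    "find_replicate_groups",
    "load_study_fixture",
]


@dataclass(frozen=True)
class Factor:
    """One continuous design factor with natural-unit bounds."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"factor {self.name!r}: bounds must be finite")
        if not self.high > self.low:
            raise ValueError(
                f"factor {self.name!r}: high ({self.high}) must exceed low ({self.low})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered collection of factors defining the design region (a box)."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if len(self.factors) < 2:
            raise ValueError("a factor space needs at least 2 factors")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"factor names must be unique, got {names}")

    @classmethod
    def from_bounds(
        cls, bounds: Sequence[tuple[str, float, float]] | dict[str, tuple[float, float]]
    ) -> "FactorSpace":
        if isinstance(bounds, dict):
            bounds = [(n, lo, hi) for n, (lo, hi) in bounds.items()]
        return cls(tuple(Factor(n, lo, hi) for n, lo, hi in bounds))

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def lows(self) -> np.ndarray:
        return np.array([f.low for f in self.factors], dtype=float)

    @property
    def highs(self) -> np.ndarray:
        return np.array([f.high for f in self.factors], dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.factors], dtype=float)

    @property
    def half_ranges(self) -> np.ndarray:
        return np.array([f.half_range for f in self.factors], dtype=float)

    def code(self, natural: np.ndarray) -> np.ndarray:
        """Map natural-unit point(s) to coded units; accepts (k,) or (n, k)."""
        natural = np.asarray(natural, dtype=float)
        if natural.shape[-1] != self.k:
            raise ValueError(
                f"expected {self.k} coordinates, got {natural.shape[-1]}"
            )
        if not np.all(np.isfinite(natural)):
            raise ValueError("natural coordinates must be finite")
        return (natural - self.centers) / self.half_ranges

    def decode(self, coded: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`code`."""
        coded = np.asarray(coded, dtype=float)
        if coded.shape[-1] != self.k:
            raise ValueError(f"expected {self.k} coordinates, got {coded.shape[-1]}")
        if not np.all(np.isfinite(coded)):
            raise ValueError("coded coordinates must be finite")
        return self.centers + coded * self.half_ranges

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
            for f in self.factors
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorSpace":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(
                Factor(d["name"], d["low"], d["high"], d.get("units", ""))
                for d in payload
            )
        )


# Convenience aliases kept module-level so they read naturally at call sites.
def code_point(space: FactorSpace, natural: Sequence[float]) -> np.ndarray:
    return space.code(np.asarray(natural, dtype=float))


def decode_point(space: FactorSpace, coded: Sequence[float]) -> np.ndarray:
    return space.decode(np.asarray(coded, dtype=float))


@dataclass
class DesignTable:
    """Runs-by-factors design with optional observed/predicted responses.

    The canonical storage is a DataFrame with one natural-unit column per
    factor plus optional ``response``, ``predicted`` and ``r_student``
    columns, indexed by ``run_id``.  Coded levels are derived views.
    """

    space: FactorSpace
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [n for n in self.space.names if n not in self.data.columns]
        if missing:
            raise ValueError(f"design table missing factor columns {missing}")
        if self.data.index.name != "run_id":
            if "run_id" in self.data.columns:
                self.data = self.data.set_index("run_id")
            else:
                self.data = self.data.copy()
                self.data.index = pd.RangeIndex(1, len(self.data) + 1, name="run_id")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def natural(self) -> np.ndarray:
        return self.data[self.space.names].to_numpy(dtype=float)

    @property
    def coded(self) -> np.ndarray:
        return self.space.code(self.natural)

    @property
    def response(self) -> np.ndarray:
        if "response" not in self.data.columns:
            raise ValueError("design table has no response column")
        return self.data["response"].to_numpy(dtype=float)

    @classmethod
    def from_coded(
        cls,
        space: FactorSpace,
        coded: np.ndarray,
        response: np.ndarray | None = None,
    ) -> "DesignTable":
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        df = pd.DataFrame(space.decode(coded), columns=space.names)
        if response is not None:
            df["response"] = np.asarray(response, dtype=float)
        return cls(space, df)

    def with_response(self, response: np.ndarray) -> "DesignTable":
        df = self.data.copy()
        df["response"] = np.asarray(response, dtype=float)
        return DesignTable(self.space, df)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        coded = self.coded
        for j, name in enumerate(self.space.names):
            out[f"coded_{name}"] = coded[:, j]
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, space: FactorSpace) -> "DesignTable":
        df = pd.read_csv(path)
        keep = [c for c in df.columns if not c.startswith("coded_")]
        table = cls(space, df[keep])
        # consistency check when coded columns are present in the file
        coded_cols = [f"coded_{n}" for n in space.names]
        if all(c in df.columns for c in coded_cols):
            stored = df[coded_cols].to_numpy(dtype=float)
            if not np.allclose(stored, table.coded, atol=1e-9):
                raise ValueError("stored coded levels disagree with the coding map")
        return table


@dataclass(frozen=True)
class ReplicateGrouping:
    """Partition of runs into groups with identical coded settings."""

    groups: tuple[tuple[int, ...], ...]  # run_ids

    @property
    def pure_error_df(self) -> int:
        return sum(len(g) - 1 for g in self.groups)

    @property
    def replicated(self) -> tuple[tuple[int, ...], ...]:
        return tuple(g for g in self.groups if len(g) > 1)


def find_replicate_groups(design: DesignTable, tol: float = 0.0) -> ReplicateGrouping:
    """Group runs sharing identical coded levels across all factors.

    With ``tol == 0`` (default, appropriate for integer-coded designs) grouping
    uses exact equality; a positive ``tol`` merges runs whose coded levels
    round to the same multiple of ``tol``.
    """
    if len(design) == 0:
        raise ValueError("design table is empty")
    coded = design.coded
    if tol > 0:
        coded = np.round(coded / tol) * tol
    keys: dict[tuple, list[int]] = {}
    for run_id, row in zip(design.data.index, coded):
        keys.setdefault(tuple(row), []).append(int(run_id))
    return ReplicateGrouping(tuple(tuple(v) for v in keys.values()))


def face_centered_ccd(
    space: FactorSpace, n_center: int = 1, fraction: str = "full"
) -> DesignTable:
    """Generate a face-centred (alpha = 1) central-composite design.

    The design combines a two-level factorial portion at the +-1 corners
    (full ``2^k`` or a resolution-V half fraction ``2^(k-1)`` with defining
    relation ``x_k = x_1 x_2 ... x_(k-1)``), ``2k`` axial points on the face
    centres, and ``n_center`` replicated centre runs.  Every coded level is
    in {-1, 0, +1}, which supports a full quadratic fit with three-level
    factors.
    """
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    if fraction not in ("full", "half"):
        raise ValueError(f"fraction must be 'full' or 'half', got {fraction!r}")
    k = space.k
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    if fraction == "half":
        # keep corners whose coordinate product is +1 (principal fraction)
        corners = corners[np.prod(corners, axis=1) > 0]
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -1.0
        axial[2 * i + 1, i] = 1.0
    center = np.zeros((n_center, k))
    coded = np.vstack([corners, axial, center])
    return DesignTable.from_coded(space, coded)


# ---------------------------------------------------------------------------
# Study fixture: the published 33-run lipase fermentation CCD
# ---------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"

#: Fermentation factor ranges used throughout the study fixture.
LIPASE_FACTORS = (
    Factor("temperature", 30.0, 40.0, "degC"),
    Factor("oil_concentration", 10.0, 14.0, "%"),
    Factor("inoculum_size", 8.0, 12.0, "%"),
    Factor("pH", 7.0, 9.0, ""),
    Factor("incubation_time", 2.0, 4.0, "h"),
)


def load_study_fixture(variant: int = 33) -> tuple[FactorSpace, DesignTable]:
    """Load the published lipase-fermentation CCD with observed responses.

    The table ships verbatim as printed: 33 runs over five factors at three
    levels each, with the observed lipase activity (U/mL) plus the published
    model predictions and R-studentized residuals retained for reference in
    columns ``predicted`` and ``r_student``.

    ``variant=33`` returns all printed rows (7 centre replicates).
    ``variant=32`` drops the final duplicated centre row, matching the
    published ANOVA's total df of 31 (6 centre replicates); the source
    tables are ambiguous about which view was used, so both are exposed.
    """
    if variant not in (33, 32):
        raise ValueError("variant must be 33 or 32")
    space = FactorSpace(LIPASE_FACTORS)
    table = DesignTable.from_csv(_DATA_DIR / "lipase_ccd.csv", space)
    if variant == 32:
        table = DesignTable(space, table.data.drop(index=33))
    return space, table
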