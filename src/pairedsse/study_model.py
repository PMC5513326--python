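"""Domain types for paired comparative diagnostic accuracy studies.

A paired study applies two index tests (A and B) to every subject and
classifies each subject as diseased or non-diseased by a gold standard.
The data are eight cell counts: within each gold-standard stratum, a 2x2
table of the two tests' results.  Conventionally test A is the new test
whose superiority over the comparator B is being assessed.

Cell letters (fixed by the design):

    diseased:      A = both positive,  B = A+/B-,  C = A-/B+,  D = both negative
    non-diseased:  E = both positive,  F = A+/B-,  G = A-/B+,  H = both negative
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass, fields

from .errors import DegenerateDataError, InputError

__all__ = [
    "CELL_NAMES",
    "PairedCounts",
    "DesignHypotheses",
    "ObservedRates",
    "read_counts",
    "write_counts",
    "observed_rates",
]

#: Canonical cell names used in every file format.
CELL_NAMES = ("n_A", "n_B", "n_C", "n_D", "n_E", "n_F", "n_G", "n_H")


@dataclass(frozen=True)
class PairedCounts:
    """The eight observed cells of a paired diagnostic study.

    Attributes use lowercase letters; file formats use the canonical
    uppercase-letter keys of :data:`CELL_NAMES`.
    """

    n_a: int
    n_b: int
    n_c: int
    n_d: int
    n_e: int
    n_f: int
    n_g: int
    n_h: int

    def __post_init__(self) -> None:
        for f, cell in zip(fields(self), CELL_NAMES):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                raise InputError(f"cell {cell} must be an integer, got {v!r}")
            if not isinstance(v, int):
                # numpy integers are fine; coerce them
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise InputError(f"cell {cell} must be an integer, got {v!r}") from None
                if iv != v:
                    raise InputError(f"cell {cell} must be an integer, got {v!r}")
                object.__setattr__(self, f.name, iv)
            if getattr(self, f.name) < 0:
                raise InputError(f"cell {cell} must be non-negative, got {v!r}")

    @property
    def n_diseased(self) -> int:
        return self.n_a + self.n_b + self.n_c + self.n_d

    @property
    def n_nondiseased(self) -> int:
        return self.n_e + self.n_f + self.n_g + self.n_h

    @property
    def n_total(self) -> int:
        return self.n_diseased + self.n_nondiseased

    @property
    def diseased_cells(self) -> tuple[int, int, int, int]:
        """(both+, A+/B-, A-/B+, both-) for the diseased stratum."""
        return (self.n_a, self.n_b, self.n_c, self.n_d)

    @property
    def nondiseased_cells(self) -> tuple[int, int, int, int]:
        """(both+, A+/B-, A-/B+, both-) for the non-diseased stratum."""
        return (self.n_e, self.n_f, self.n_g, self.n_h)

    def to_dict(self) -> dict[str, int]:
        """Map with the canonical uppercase cell keys."""
        return dict(zip(CELL_NAMES, self.as_tuple()))

    def as_tuple(self) -> tuple[int, ...]:
        return (self.n_a, self.n_b, self.n_c, self.n_d,
                self.n_e, self.n_f, self.n_g, self.n_h)

    @classmethod
    def from_dict(cls, d: dict) -> "PairedCounts":
        missing = [k for k in CELL_NAMES if k not in d]
        if missing:
            raise InputError(f"missing cell(s): {', '.join(missing)}")
        vals = []
        for k in CELL_NAMES:
            v = d[k]
            if isinstance(v, bool):
                raise InputError(f"cell {k} must be an integer, got {v!r}")
            if isinstance(v, float):
                if not v.is_integer():
                    raise InputError(f"cell {k} must be an integer, got {v!r}")
                v = int(v)
            if isinstance(v, str):
                try:
                    v = int(v)
                except ValueError:
                    raise InputError(f"cell {k} must be an integer, got {v!r}")
            vals.append(v)
        return cls(*vals)


@dataclass(frozen=True)
class DesignHypotheses:
    """Hypothesised design parameters for a paired superiority study.

    Parameters
    ----------
    alpha : float
        Two-sided type-I error rate.
    beta : float
        Type-II error rate; nominal power is ``1 - beta``.
    tpr_a, tpr_b : float
        Hypothesised sensitivities of test A (new) and test B (comparator).
    tnr_a, tnr_b : float
        Hypothesised specificities.
    prevalence : float
        Expected disease prevalence pi in the study population.
    """

    alpha: float
    beta: float
    tpr_a: float
    tpr_b: float
    tnr_a: float
    tnr_b: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie strictly in (0, 1), got {v}")
        for name in ("tpr_a", "tpr_b", "tnr_a", "tnr_b", "prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie strictly in (0, 1), got {v}")

    @property
    def gamma1(self) -> float:
        """Ratio of sensitivities TPR_A / TPR_B."""
        return self.tpr_a / self.tpr_b

    @property
    def gamma2(self) -> float:
        """Ratio of specificities TNR_A / TNR_B."""
        return self.tnr_a / self.tnr_b

    def to_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha, "beta": self.beta,
            "tpr_a": self.tpr_a, "tpr_b": self.tpr_b,
            "tnr_a": self.tnr_a, "tnr_b": self.tnr_b,
            "prevalence": self.prevalence,
            "gamma1": self.gamma1, "gamma2": self.gamma2,
        }


@dataclass(frozen=True)
class ObservedRates:
    """Empirical rates derived from a :class:`PairedCounts` table.

    ``tppr_hat`` is the proportion of diseased subjects positive on both
    tests; ``tnnr_hat`` the proportion of non-diseased subjects negative on
    both.  Joint rates can never exceed either marginal.
    """

    tpr_a_hat: float
    tpr_b_hat: float
    tppr_hat: float
    tnr_a_hat: float
    tnr_b_hat: float
    tnnr_hat: float
    prevalence_hat: float

    def to_dict(self) -> dict[str, float]:
        return {
            "tpr_a_hat": self.tpr_a_hat, "tpr_b_hat": self.tpr_b_hat,
            "tppr_hat": self.tppr_hat, "tnr_a_hat": self.tnr_a_hat,
            "tnr_b_hat": self.tnr_b_hat, "tnnr_hat": self.tnnr_hat,
            "prevalence_hat": self.prevalence_hat,
        }


def observed_rates(counts: PairedCounts) -> ObservedRates:
    """Empirical sensitivities, specificities, joint rates and prevalence.

    Requires both strata to be non-empty; proportions are carried at full
    floating precision (never rounded internally).
    """
    nd, nn = counts.n_diseased, counts.n_nondiseased
    if nd == 0:
        raise DegenerateDataError("diseased stratum is empty; sensitivities undefined")
    if nn == 0:
        raise DegenerateDataError("non-diseased stratum is empty; specificities undefined")
    return ObservedRates(
        tpr_a_hat=(counts.n_a + counts.n_b) / nd,
        tpr_b_hat=(counts.n_a + counts.n_c) / nd,
        tppr_hat=counts.n_a / nd,
        tnr_a_hat=(counts.n_g + counts.n_h) / nn,
        tnr_b_hat=(counts.n_f + counts.n_h) / nn,
        tnnr_hat=counts.n_h / nn,
        prevalence_hat=nd / counts.n_total,
    )


def _infer_format(source, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "json"):
            raise InputError(f"unknown counts format {fmt!r} (expected csv or json)")
        return fmt
    name = str(source)
    if name.endswith(".csv"):
        return "csv"
    if name.endswith(".json"):
        return "json"
    raise InputError("cannot infer counts format; pass format='csv' or 'json'")


def read_counts(source, format: str | None = None) -> PairedCounts:
    """Read an eight-cell paired count table from CSV or JSON.

    CSV: a single header row ``n_A,...,n_H`` and one data row.
    JSON: a flat object with the same keys.  ``source`` may be a path or a
    literal text string (text requires ``format``).
    """
    text: str
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
        fmt = _infer_format(source, format)
    else:
        if format is None:
            raise InputError(f"no such file: {source!r} (pass format= to parse literal text)")
        text = str(source)
        fmt = _infer_format("", format)

    if fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise InputError(f"unparseable JSON counts: {e}") from e
        if not isinstance(data, dict):
            raise InputError("JSON counts must be a flat object of cells")
        return PairedCounts.from_dict(data)

    rows = list(csv.DictReader(io.StringIO(text)))
    if not rows:
        raise InputError("CSV counts file has no data row")
    if len(rows) > 1:
        raise InputError("CSV counts file must contain exactly one data row")
    row = {k: v for k, v in rows[0].items() if k is not None}
    if any(v is None for v in row.values()):
        raise InputError("CSV data row has fewer fields than the header")
    return PairedCounts.from_dict(row)


def write_counts(counts: PairedCounts, path, format: str | None = None) -> None:
    """Write a count table as CSV (one header + one data row) or JSON."""
    fmt = _infer_format(path, format)
    d = counts.to_dict()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fmt == "json":
            json.dump(d, fh, indent=2)
            fh.write("\n")
        else:
            w = csv.DictWriter(fh, fieldnames=list(CELL_NAMES))
            w.writeheader()
            w.writerow(d)
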