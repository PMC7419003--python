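"""Long-format panel I/O: validation, design-matrix assembly, result serialization.

A panel here is a long-format table with one record per subject-visit, a
nonnegative response and numeric covariates.  Subjects are grouped into
contiguous, ordered blocks; the design matrix always carries an explicit
intercept column, and interaction columns are formed as elementwise products
of named parent covariates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tweedieqr")

#: Linear trend coding for a 1..4 visit index, centred and equally spaced.
VISIT_CODES = (-0.3, -0.1, 0.1, 0.3)


class PanelValidationError(ValueError):
    """Raised when input data violate the panel contract."""


class PanelConfigError(KeyError):
    """Raised when requested columns are absent from the input file."""


@dataclass
class PanelData:
    """Subject-indexed repeated measures.

    Attributes
    ----------
    subject_ids : np.ndarray
        Per-record subject label; records of a subject are contiguous.
    y : np.ndarray
        Nonnegative response per record.
    X : np.ndarray
        (N, p) design matrix including the intercept column.
    columns : list of str
        Design-matrix column names (``"Intercept"`` first).
    n_i : np.ndarray
        Records per subject, in subject order.
    """

    subject_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    n_i: np.ndarray = field(init=False)
    starts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.ndim != 1 or self.X.ndim != 2 or len(self.y) != len(self.X):
            raise PanelValidationError("y and X must align record-wise")
        if len(self.subject_ids) != len(self.y):
            raise PanelValidationError("subject ids must align with records")
        if np.any(self.y < 0) or not np.all(np.isfinite(self.y)):
            raise PanelValidationError("response must be finite and nonnegative")
        if not np.all(np.isfinite(self.X)):
            raise PanelValidationError("covariates must be finite")
        # contiguity: each label appears in exactly one run
        ids = self.subject_ids
        change = np.concatenate(([True], ids[1:] != ids[:-1]))
        labels = ids[change]
        if len(set(labels.tolist())) != len(labels):
            raise PanelValidationError("records of a subject must be contiguous")
        self.starts = np.flatnonzero(change)
        bounds = np.concatenate((self.starts, [len(ids)]))
        self.n_i = np.diff(bounds)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise PanelValidationError("design matrix is rank deficient")

    @property
    def m(self) -> int:
        """Number of subjects."""
        return len(self.n_i)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject labels in panel order."""
        return self.subject_ids[self.starts]

    def blocks(self) -> Iterator[slice]:
        """Record slices, one per subject, in panel order."""
        for s, n in zip(self.starts, self.n_i):
            yield slice(int(s), int(s + n))

    def subset(self, subject_idx: Sequence[int]) -> "PanelData":
        """New panel from subject positions (repeats allowed, for bootstrap).

        Repeated subjects are relabelled so each draw forms its own block.
        """
        rows, ids = [], []
        for k, i in enumerate(subject_idx):
            s = int(self.starts[i])
            n = int(self.n_i[i])
            rows.append(np.arange(s, s + n))
            ids.append(np.full(n, k))
        rows = np.concatenate(rows)
        return PanelData(
            subject_ids=np.concatenate(ids),
            y=self.y[rows],
            X=self.X[rows],
            columns=list(self.columns),
        )


@dataclass
class FitResult:
    """Tabular fit output: one row per coefficient plus a dispersion block."""

    names: list[str]
    estimates: np.ndarray | None
    se: np.ndarray | None
    ci_level: float
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    dispersions: dict[str, float]
    converged: bool
    n_iter: int
    boot_se: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if self.estimates is None:
            return pd.DataFrame(
                columns=["name", "EP", "SE", "CI_lower", "CI_upper"]
            )
        d = {
            "name": self.names,
            "EP": np.asarray(self.estimates, float),
            "SE": np.asarray(self.se, float),
            "CI_lower": np.asarray(self.ci_lower, float),
            "CI_upper": np.asarray(self.ci_upper, float),
        }
        if self.boot_se is not None:
            d["boot_SE"] = np.asarray(self.boot_se, float)
        return pd.DataFrame(d)


def read_panel(
    path: str | Path,
    subject_col: str,
    response_col: str,
    covariate_cols: Sequence[str],
    interaction_pairs: Sequence[tuple[str, str]] = (),
    visit_recode_col: str | None = None,
    log_transform_cols: Sequence[str] = (),
    quarter_log_cols: Sequence[str] = (),
) -> PanelData:
    """Read a long-format CSV into a :class:`PanelData`.

    Parameters
    ----------
    interaction_pairs : pairs of covariate names
        Each pair adds a column equal to the elementwise product of its
        parents, named ``"a.b"``.
    visit_recode_col : optional
        A column holding a 1..4 visit index to be recoded onto the centred
        linear trend ``(-0.3, -0.1, 0.1, 0.3)``.
    log_transform_cols : optional
        Columns replaced by their natural log (e.g. age).
    quarter_log_cols : optional
        Columns replaced by ``log(x / 4)`` (e.g. an 8-week baseline count
        rescaled to the 2-week observation window).

    Records with any missing field are dropped (count logged); subjects are
    regrouped in order of first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    needed = [subject_col, response_col, *covariate_cols]
    if visit_recode_col is not None and visit_recode_col not in needed:
        needed.append(visit_recode_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PanelConfigError(f"missing columns: {missing}")
    df = df[needed]
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d records with missing fields", n0 - len(df))
    if df.empty:
        raise PanelValidationError("no complete records after filtering")

    y = pd.to_numeric(df[response_col], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise PanelValidationError(f"non-numeric response in '{response_col}'")
    if np.any(y < 0):
        raise PanelValidationError("negative response values")

    work = df.copy()
    if visit_recode_col is not None:
        v = pd.to_numeric(work[visit_recode_col], errors="coerce").to_numpy(float)
        if not np.all(np.isin(v, [1, 2, 3, 4])):
            raise PanelValidationError("visit index must lie in 1..4 for recoding")
        work[visit_recode_col] = np.asarray(VISIT_CODES)[v.astype(int) - 1]
    for c in quarter_log_cols:
        work[c] = np.log(pd.to_numeric(work[c]).to_numpy(float) / 4.0)
    for c in log_transform_cols:
        work[c] = np.log(pd.to_numeric(work[c]).to_numpy(float))

    cols = ["Intercept", *covariate_cols]
    parts = [np.ones(len(work))]
    for c in covariate_cols:
        col = pd.to_numeric(work[c], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(col)):
            raise PanelValidationError(f"non-numeric covariate in '{c}'")
        parts.append(col)
    for a, b in interaction_pairs:
        ia, ib = cols.index(a), cols.index(b)
        parts.append(parts[ia] * parts[ib])
        cols.append(f"{a}.{b}")
    X = np.column_stack(parts)

    # group subjects in order of first appearance, contiguously
    subj = work[subject_col].to_numpy()
    order = np.argsort(pd.factorize(subj)[0], kind="stable")
    return PanelData(subject_ids=subj[order], y=y[order], X=X[order], columns=cols)


def write_fit(result: FitResult, path: str | Path) -> None:
    """Serialize a fit to CSV (coefficient table + dispersion block) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "converged": bool(result.converged),
            "n_iter": int(result.n_iter),
            "ci_level": float(result.ci_level),
            "coefficients": result.to_frame().to_dict(orient="records"),
            "dispersions": {k: float(v) for k, v in result.dispersions.items()},
            "extra": result.extra,
        }
        path.write_text(json.dumps(obj, indent=2))
        return
    frame = result.to_frame()
    disp = pd.DataFrame(
        {
            "name": list(result.dispersions),
            "EP": [float(v) for v in result.dispersions.values()],
        }
    )
    meta = pd.DataFrame(
        {"name": ["converged", "n_iter"], "EP": [float(result.converged), result.n_iter]}
    )
    out = pd.concat([frame, disp, meta], ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")


def read_fit(path: str | Path) -> FitResult:
    """Inverse of :func:`write_fit` for JSON files (used for round-tripping)."""
    obj = json.loads(Path(path).read_text())
    rows = obj["coefficients"]
    if rows:
        est = np.array([r["EP"] for r in rows])
        se = np.array([r["SE"] for r in rows])
        lo = np.array([r["CI_lower"] for r in rows])
        hi = np.array([r["CI_upper"] for r in rows])
        boot = (
            np.array([r["boot_SE"] for r in rows]) if "boot_SE" in rows[0] else None
        )
        names = [r["name"] for r in rows]
    else:
        est = se = lo = hi = boot = None
        names = []
    return FitResult(
        names=names,
        estimates=est,
        se=se,
        ci_level=obj["ci_level"],
        ci_lower=lo,
        ci_upper=hi,
        dispersions=obj["dispersions"],
        converged=obj["converged"],
        n_iter=obj["n_iter"],
        boot_se=boot,
        extra=obj.get("extra", {}),
    )


def load_epilepsy(path: str | Path) -> PanelData:
    """Load the classic 59-patient seizure panel from its raw CSV layout.

    Expects columns ``subject, visit, y, base, trt, age`` with raw (untransformed)
    values; applies the standard covariate coding: Base = log(baseline/4),
    Age = log(age), Visit on the centred linear trend, plus Base.Trt.
    """
    return read_panel(
        path,
        subject_col="subject",
        response_col="y",
        covariate_cols=["base", "trt", "age", "visit"],
        interaction_pairs=[("base", "trt")],
        visit_recode_col="visit",
        quarter_log_cols=["base"],
        log_transform_cols=["age"],
    )
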