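"""Dataset container and delimited-text IO for coded case-control covariate tables.

Covariates are integer-coded categorical or ordinal exposures. Missingness is
represented internally by the sentinel :data:`MISSING` (-1) together with an
explicit boolean mask, so downstream code never has to re-parse the user's
missing-value token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Sentinel stored in ``X`` where a covariate value is missing.
MISSING: int = -1

NOMINAL = "nominal"
ORDINAL = "ordinal"


@dataclass(frozen=True)
class CovariateSpec:
    """Metadata for one coded covariate.

    Parameters
    ----------
    name : str
        Column name in the source table.
    kind : {"nominal", "ordinal"}
        Whether the categories are unordered or carry an agreed order
        ``0 .. n_categories - 1``.
    n_categories : int
        Number of categories ``M_p`` (at least 2).
    category_labels : tuple of str, optional
        Original labels, retained for reporting only.
    """

    name: str
    kind: str
    n_categories: int
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (NOMINAL, ORDINAL):
            raise ValueError(f"covariate {self.name!r}: kind must be "
                             f"'nominal' or 'ordinal', got {self.kind!r}")
        if self.n_categories < 2:
            raise ValueError(f"covariate {self.name!r}: n_categories must be "
                             f">= 2, got {self.n_categories}")
        if (self.category_labels is not None
                and len(self.category_labels) != self.n_categories):
            raise ValueError(f"covariate {self.name!r}: got "
                             f"{len(self.category_labels)} labels for "
                             f"{self.n_categories} categories")


@dataclass
class ProfileDataset:
    """A validated subjects-by-covariates case-control dataset.

    Attributes
    ----------
    X : ndarray of shape (n, P), dtype int
        Covariate matrix, entries in ``0 .. M_p - 1`` or :data:`MISSING`.
    y : ndarray of shape (n,), dtype int
        Binary outcome (case = 1, control = 0); never missing.
    W : ndarray of shape (n, Q), dtype float
        Confounder matrix; ``Q`` may be 0.
    specs : list of CovariateSpec
    missing_mask : ndarray of shape (n, P), dtype bool
        True exactly where ``X`` holds the missing sentinel.
    """

    X: np.ndarray
    y: np.ndarray
    W: np.ndarray
    specs: list[CovariateSpec]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    confounder_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, P = self.X.shape
        if self.W is None:
            self.W = np.zeros((n, 0))
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim == 1:
            self.W = self.W[:, None]
        if self.missing_mask is None:
            self.missing_mask = self.X == MISSING
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n, P = self.X.shape
        if len(self.specs) != P:
            raise ValueError(f"{len(self.specs)} specs for {P} covariate columns")
        if self.y.shape != (n,):
            raise ValueError("y length does not match X")
        if self.W.shape[0] != n:
            raise ValueError("W length does not match X")
        if self.missing_mask.shape != (n, P):
            raise ValueError("missing_mask shape does not match X")
        if not np.array_equal(self.missing_mask, self.X == MISSING):
            raise ValueError("missing_mask inconsistent with X sentinel entries")
        uniq = np.unique(self.y)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("y must contain only 0 and 1")
        if not (np.any(self.y == 1) and np.any(self.y == 0)):
            raise ValueError("need at least one case and one control")
        for p, spec in enumerate(self.specs):
            col = self.X[:, p]
            obs = col[~self.missing_mask[:, p]]
            if obs.size == 0:
                raise ValueError(f"covariate {spec.name!r} is entirely missing")
            if obs.min() < 0 or obs.max() >= spec.n_categories:
                bad = np.where((col >= 0) & (col >= spec.n_categories)
                               | ((col < 0) & (col != MISSING)))[0]
                row = int(bad[0]) if bad.size else int(np.argmax(obs < 0))
                raise ValueError(
                    f"covariate {spec.name!r}: category out of range "
                    f"0..{spec.n_categories - 1} at row {row}")
        if self.W.size and not np.all(np.isfinite(self.W)):
            raise ValueError("confounders contain non-finite values")

    # -- conveniences -------------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_confounders(self) -> int:
        return self.W.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.y.sum())

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([s.n_categories for s in self.specs])

    def subset(self, idx: np.ndarray) -> "ProfileDataset":
        """Row subset (copies)."""
        idx = np.asarray(idx)
        return ProfileDataset(self.X[idx].copy(), self.y[idx].copy(),
                              self.W[idx].copy(), list(self.specs),
                              confounder_names=list(self.confounder_names))

    def complete_cases(self) -> "ProfileDataset":
        """Subjects with no missing covariate entries."""
        return self.subset(np.where(~self.missing_mask.any(axis=1))[0])

    def to_frame(self, missing_code: str = "NA") -> pd.DataFrame:
        cols: dict[str, object] = {}
        for p, spec in enumerate(self.specs):
            col = self.X[:, p].astype(object)
            col[self.missing_mask[:, p]] = missing_code
            cols[spec.name] = col
        cols["outcome"] = self.y
        for q, name in enumerate(self.confounder_names
                                 or [f"w{q}" for q in range(self.n_confounders)]):
            cols[name] = self.W[:, q]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# IO


def _read_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def dataset_config(data: ProfileDataset, missing_code: str = "NA") -> dict:
    """Covariate-declaration config matching :meth:`ProfileDataset.to_frame`."""
    return {
        "outcome": "outcome",
        "missing_code": missing_code,
        "covariates": [
            {"name": s.name, "kind": s.kind, "n_categories": int(s.n_categories)}
            for s in data.specs
        ],
        "confounders": list(data.confounder_names),
    }


def write_dataset(data: ProfileDataset, path, missing_code: str = "NA",
                  sep: str = ",") -> None:
    """Write a dataset back to delimited text (round-trips with load_dataset)."""
    data.to_frame(missing_code).to_csv(path, index=False, sep=sep)


def load_dataset(path, config, missing_code: str | None = None,
                 sep: str = ",") -> ProfileDataset:
    """Load a delimited-text table into a validated :class:`ProfileDataset`.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.
    config : dict or path to YAML/JSON
        Declares ``outcome`` (column name), ``covariates`` (list of dicts with
        ``name``, ``kind``, ``n_categories`` and optionally ``labels``),
        optional ``confounders`` (column names), ``missing_code`` and
        ``center_confounders``.
    missing_code : str, optional
        Overrides the config's missing-value token (default "NA").

    Notes
    -----
    Rows with a missing outcome are dropped (count logged); rows with missing
    confounder values are dropped with a warning — covariates are the only
    quantities imputed downstream. Category codes must be integers in
    ``0 .. n_categories - 1`` unless ``labels`` are declared, in which case
    labels are re-coded to 0-based integers in the declared order.
    """
    cfg = _read_config(config)
    mc = missing_code if missing_code is not None else cfg.get("missing_code", "NA")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]

    outcome_col = cfg["outcome"]
    cov_cfg = cfg["covariates"]
    conf_cols = list(cfg.get("confounders") or [])
    for col in [outcome_col, *[c["name"] for c in cov_cfg], *conf_cols]:
        if col not in df.columns:
            raise ValueError(f"unknown column {col!r} (file has {list(df.columns)})")

    # outcome: reject missing rows with a logged count
    out_raw = df[outcome_col].str.strip()
    bad_outcome = (out_raw == mc) | (out_raw == "")
    if bad_outcome.any():
        logger.info("dropped %d rows with missing outcome", int(bad_outcome.sum()))
        df = df.loc[~bad_outcome]
        out_raw = out_raw.loc[~bad_outcome]

    # confounders: drop rows with missing values (not imputed)
    W_raw = df[conf_cols].apply(lambda s: s.str.strip()) if conf_cols else None
    if conf_cols:
        bad_conf = ((W_raw == mc) | (W_raw == "")).any(axis=1)
        if bad_conf.any():
            logger.warning("dropped %d rows with missing confounders",
                           int(bad_conf.sum()))
            df = df.loc[~bad_conf]
            out_raw = out_raw.loc[~bad_conf]
            W_raw = W_raw.loc[~bad_conf]

    y = pd.to_numeric(out_raw).to_numpy()
    n = len(df)
    specs: list[CovariateSpec] = []
    X = np.empty((n, len(cov_cfg)), dtype=np.int64)
    for p, c in enumerate(cov_cfg):
        name, kind, M = c["name"], c["kind"], int(c["n_categories"])
        labels = c.get("labels")
        raw = df[name].str.strip()
        miss = (raw == mc) | (raw == "")
        if labels is not None:
            mapping = {str(lab): i for i, lab in enumerate(labels)}
            codes = raw.map(mapping)
            bad = codes.isna() & ~miss
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ValueError(f"covariate {name!r}: unknown label "
                                 f"{raw.iloc[row]!r} at row {row}")
            col = codes.fillna(MISSING).to_numpy(dtype=np.int64)
            labels = tuple(str(lab) for lab in labels)
        else:
            vals = pd.to_numeric(raw.where(~miss, other=str(MISSING)))
            col = vals.to_numpy()
            if not np.all(col == np.floor(col)):
                row = int(np.argmax(col != np.floor(col)))
                raise ValueError(f"covariate {name!r}: non-integer code at row {row}")
            col = col.astype(np.int64)
        obs = col[~miss.to_numpy()]
        if obs.size == 0:
            raise ValueError(f"covariate {name!r} is entirely missing")
        if obs.size and (obs.min() < 0 or obs.max() >= M):
            row = int(np.argmax(((col < 0) | (col >= M)) & ~miss.to_numpy()))
            raise ValueError(f"covariate {name!r}: category out of range "
                             f"0..{M - 1} at row {row}")
        col[miss.to_numpy()] = MISSING
        X[:, p] = col
        specs.append(CovariateSpec(name, kind, M, labels))

    if conf_cols:
        W = W_raw.apply(pd.to_numeric).to_numpy(dtype=float)
        if cfg.get("center_confounders"):
            W = W - W.mean(axis=0)
    else:
        W = np.zeros((n, 0))

    return ProfileDataset(X, y, W, specs, confounder_names=conf_cols)


def summarize_dataset(data: ProfileDataset) -> dict:
    """Marginal summaries: per-covariate category frequencies (among the
    non-missing entries), case/control counts, and missingness counts."""
    freqs = {}
    missing = {}
    for p, spec in enumerate(data.specs):
        obs = data.X[~data.missing_mask[:, p], p]
        counts = np.bincount(obs, minlength=spec.n_categories).astype(float)
        freqs[spec.name] = counts / counts.sum()
        missing[spec.name] = int(data.missing_mask[:, p].sum())
    return {
        "n": data.n,
        "n_cases": data.n_cases,
        "n_controls": data.n_controls,
        "case_fraction": data.n_cases / data.n,
        "n_confounders": data.n_confounders,
        "category_frequencies": freqs,
        "missing_counts": missing,
    }
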