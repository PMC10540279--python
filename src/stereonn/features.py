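"""Feature-table assembly, min-max normalisation and dimensionality reduction.

A :class:`FeatureTable` is a ligand x feature matrix (pandas-backed) carrying
per-feature provenance tags (geometric / electronic / dispersion / other) and
optional per-ligand selectivity labels.  Three reduction routes are offered,
mirroring the options typically compared for small-data regression:

* manual selection -- rank features by |Pearson R| against a selectivity
  metric and keep the top k;
* PCA -- scores on the top variance-ordered components;
* Sammon mapping -- a nonlinear embedding minimising the distance-weighted
  stress  E = (1/sum d_ij) * sum (d_ij - delta_ij)^2 / d_ij  by gradient
  descent with step halving, initialised from the PCA projection so the result
  is deterministic.

Normalisation parameters are always fitted on an explicit row subset so that
cross-validation folds cannot leak information from held-out ligands.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .selectivity import Metric, SelectivityRecord, parse_er, to_metric

__all__ = [
    "FeatureTable",
    "NormalizationParams",
    "SammonState",
    "PCAResult",
    "AssemblyError",
    "assemble",
    "minmax_fit",
    "minmax_apply",
    "correlation_rank",
    "select_manual",
    "pca_reduce",
    "sammon_map",
]

PROVENANCE_ORDER = ("geometric", "electronic", "dispersion", "other")


class AssemblyError(ValueError):
    """Feature table could not be assembled (missing ligands, duplicate names...)."""


@dataclass
class FeatureTable:
    """Ligand x feature matrix with provenance tags and optional labels."""

    df: pd.DataFrame  # index: ligand_id (unique strings); columns: feature names
    provenance: dict[str, str] = field(default_factory=dict)
    labels: dict[str, SelectivityRecord] | None = None

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate ligand ids")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        if self.df.isna().any().any():
            bad = self.df.columns[self.df.isna().any()].tolist()
            raise ValueError(f"missing values in features {bad}")
        for name in self.df.columns:
            self.provenance.setdefault(name, "other")
        if self.labels is not None:
            missing = set(self.df.index) - set(self.labels)
            if missing:
                raise ValueError(f"ligands without labels: {sorted(missing)}")

    # -- accessors ---------------------------------------------------------
    @property
    def ligand_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def n_ligands(self) -> int:
        return len(self.df.index)

    def label_vector(self, metric: Metric | str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table has no labels")
        return np.array([to_metric(self.labels[i], metric) for i in self.df.index])

    def subset_rows(self, ids: list[str]) -> "FeatureTable":
        labels = {i: self.labels[i] for i in ids} if self.labels else None
        return FeatureTable(self.df.loc[ids].copy(), dict(self.provenance), labels)

    def restrict(self, features: list[str]) -> "FeatureTable":
        unknown = [f for f in features if f not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown features {unknown}")
        prov = {f: self.provenance[f] for f in features}
        return FeatureTable(self.df[features].copy(), prov,
                            dict(self.labels) if self.labels else None)

    def sorted_by_id(self) -> "FeatureTable":
        return self.subset_rows(sorted(self.df.index))

    # -- CSV I/O -----------------------------------------------------------
    def to_csv(self) -> str:
        """Wide CSV with a one-line provenance header and, if labelled, an
        ``er`` column rendered as "R:S"."""
        prov = ",".join(f"{c}={self.provenance[c]}" for c in self.df.columns)
        out = self.df.copy()
        out.index.name = "ligand_id"
        if self.labels is not None:
            out["er"] = [
                f"{self.labels[i].r_percent:.6g}:{self.labels[i].s_percent:.6g}"
                for i in out.index
            ]
        buf = io.StringIO()
        buf.write(f"#provenance: {prov}\n")
        out.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "FeatureTable":
        lines = text.splitlines()
        provenance: dict[str, str] = {}
        if lines and lines[0].startswith("#provenance:"):
            spec = lines[0][len("#provenance:"):].strip()
            if spec:
                for item in spec.split(","):
                    name, _, tag = item.partition("=")
                    provenance[name.strip()] = tag.strip() or "other"
            lines = lines[1:]
        df = pd.read_csv(io.StringIO("\n".join(lines)), index_col="ligand_id")
        df.index = df.index.astype(str)
        labels = None
        if "er" in df.columns:
            labels = {i: parse_er(str(v)) for i, v in df["er"].items()}
            df = df.drop(columns=["er"])
        return cls(df.astype(float), provenance, labels)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(geom_csv: str, aux_csv: str | None, labels_csv: str | None) -> FeatureTable:
    """Join geometric descriptors, external electronic/dispersion features and
    er labels into a single table.

    ``geom_csv`` is the long-format descriptor CSV (ligand_id, descriptor,
    role, value, units); ``aux_csv`` is a wide CSV with an optional
    ``#provenance:`` header line; ``labels_csv`` has columns ligand_id, er.
    Every ligand in the geometric table must be covered by the other sources.
    Columns are ordered geometric, electronic, dispersion, other.
    """
    geom = pd.read_csv(io.StringIO(geom_csv))
    geom["feature"] = geom["descriptor"] + "_" + geom["role"]
    if geom.duplicated(["ligand_id", "feature"]).any():
        raise AssemblyError("duplicate descriptor rows in geometric CSV")
    wide = geom.pivot(index="ligand_id", columns="feature", values="value")
    wide.index = wide.index.astype(str)
    if wide.isna().any().any():
        gaps = wide.index[wide.isna().any(axis=1)].tolist()
        raise AssemblyError(f"incomplete descriptor coverage for ligands {gaps}")
    provenance = {c: "geometric" for c in wide.columns}

    if aux_csv is not None:
        aux = FeatureTable.from_csv(aux_csv)
        aux_df = aux.df
        missing = sorted(set(wide.index) - set(aux_df.index))
        if missing:
            raise AssemblyError(f"aux table missing ligands {missing}")
        dup = sorted(set(wide.columns) & set(aux_df.columns))
        if dup:
            raise AssemblyError(f"duplicate feature names {dup}")
        for c in aux_df.columns:
            provenance[c] = aux.provenance.get(c, "electronic")
        wide = wide.join(aux_df.loc[wide.index])

    labels = None
    if labels_csv is not None:
        lab = pd.read_csv(io.StringIO(labels_csv), dtype=str)
        lab = lab.set_index("ligand_id")
        missing = sorted(set(wide.index) - set(lab.index))
        if missing:
            raise AssemblyError(f"labels missing ligands {missing}")
        labels = {i: parse_er(lab.loc[i, "er"]) for i in wide.index}

    order = sorted(
        wide.columns,
        key=lambda c: (PROVENANCE_ORDER.index(provenance.get(c, "other")), c),
    )
    wide = wide[order].sort_index()
    return FeatureTable(wide, provenance, labels)


# ---------------------------------------------------------------------------
# Min-max normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max fitted on a stated row subset; zero-range features
    are recorded as excluded rather than producing divide-by-zero columns."""

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    excluded: tuple[str, ...]

    @property
    def retained(self) -> list[str]:
        return [f for f in self.feature_names if f not in self.excluded]


def minmax_fit(t: FeatureTable, rows: list[str] | None = None) -> NormalizationParams:
    """Fit per-feature min/max on ``rows`` (all rows if None)."""
    ids = rows if rows is not None else t.ligand_ids
    if not ids:
        raise ValueError("cannot fit normalisation on an empty row subset")
    sub = t.df.loc[ids]
    mins = sub.min(axis=0).to_numpy(dtype=float)
    maxs = sub.max(axis=0).to_numpy(dtype=float)
    excluded = tuple(
        f for f, lo, hi in zip(sub.columns, mins, maxs) if hi - lo == 0.0
    )
    return NormalizationParams(tuple(sub.columns), mins, maxs, excluded)


def minmax_apply(t: FeatureTable, p: NormalizationParams) -> FeatureTable:
    """Scale x' = (x - min) / (max - min) feature-wise.

    Rows outside the fitting subset may land outside [0, 1]; they are not
    clipped.  Zero-range (excluded) features are dropped.
    """
    unknown = [f for f in t.feature_names if f not in p.feature_names]
    if unknown or set(p.feature_names) - set(t.feature_names):
        raise ValueError(
            f"feature mismatch: table has extra {unknown}, "
            f"params expect {sorted(set(p.feature_names) - set(t.feature_names))}"
        )
    keep = p.retained
    idx = [p.feature_names.index(f) for f in keep]
    scaled = (t.df[keep].to_numpy(dtype=float) - p.mins[idx]) / (
        p.maxs[idx] - p.mins[idx]
    )
    df = pd.DataFrame(scaled, index=t.df.index, columns=keep)
    prov = {f: t.provenance[f] for f in keep}
    return FeatureTable(df, prov, dict(t.labels) if t.labels else None)


# ---------------------------------------------------------------------------
# Manual selection by correlation
# ---------------------------------------------------------------------------

def correlation_rank(
    t: FeatureTable, metric: Metric | str = Metric.s_select
) -> list[tuple[str, float, bool]]:
    """Pearson R of every feature against the chosen selectivity metric.

    Returns (feature, R, zero_variance_flag) tuples ordered by |R| descending,
    ties broken alphabetically.  Zero-variance features get R = 0 and a flag
    rather than an exception.
    """
    if t.labels is None:
        raise ValueError("correlation ranking requires labels")
    if t.n_ligands < 3:
        raise ValueError("correlation ranking needs at least 3 ligands")
    y = t.label_vector(metric)
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    out = []
    for f in t.feature_names:
        x = t.df[f].to_numpy(dtype=float)
        xc = x - x.mean()
        sx = np.sqrt((xc ** 2).sum())
        if sx == 0.0 or sy == 0.0:
            out.append((f, 0.0, True))
        else:
            out.append((f, float((xc * yc).sum() / (sx * sy)), False))
    return sorted(out, key=lambda e: (-abs(e[1]), e[0]))


def select_manual(
    t: FeatureTable, k: int, ranking: list[tuple[str, float, bool]] | None = None
) -> FeatureTable:
    """Keep the top-k features by |R|; original column order is preserved."""
    if not (1 <= k <= len(t.feature_names)):
        raise ValueError(f"k must lie in [1, {len(t.feature_names)}], got {k}")
    if ranking is None:
        ranking = correlation_rank(t)
    chosen = {f for f, _, _ in ranking[:k]}
    kept = [f for f in t.feature_names if f in chosen]
    return t.restrict(kept)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    table: FeatureTable          # scores, columns PC1..PCk
    components: np.ndarray       # (k, n_features) rows are unit loadings
    mean: np.ndarray
    explained_variance: np.ndarray
    source_features: list[str]

    def reconstruct(self) -> np.ndarray:
        return self.table.values @ self.components + self.mean


def pca_reduce(t: FeatureTable, k: int) -> PCAResult:
    """Scores on the top-k variance-ordered principal components.

    Sign convention: each component is flipped so its largest-|loading| entry
    is positive, making results reproducible across SVD implementations.
    The table is expected to be normalised first.
    """
    n, p = t.df.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k must lie in [1, {min(n - 1, p)}], got {k}")
    x = t.values
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:k]
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    expl = (s[:k] ** 2) / max(n - 1, 1)
    cols = [f"PC{j + 1}" for j in range(k)]
    df = pd.DataFrame(scores, index=t.df.index, columns=cols)
    prov = {c: "other" for c in cols}
    table = FeatureTable(df, prov, dict(t.labels) if t.labels else None)
    return PCAResult(table, comps, mean, expl, t.feature_names)


# ---------------------------------------------------------------------------
# Sammon mapping
# ---------------------------------------------------------------------------

@dataclass
class SammonState:
    """Configuration and trace for a Sammon mapping run."""

    target_dim: int = 2
    learning_rate: float = 0.3
    max_iters: int = 500
    seed: int = 0
    rel_tol: float = 1e-9
    stress_trace: list[float] = field(default_factory=list)
    jittered: bool = False


def _sammon_stress_grad(y: np.ndarray, d: np.ndarray, c: float):
    delta = squareform(pdist(y))
    np.fill_diagonal(delta, 1.0)  # diagonal never used
    dm = d.copy()
    np.fill_diagonal(dm, 1.0)
    diff = dm - delta
    iu = np.triu_indices_from(dm, k=1)
    stress = float((diff[iu] ** 2 / dm[iu]).sum() / c)
    w = diff / (dm * delta)
    np.fill_diagonal(w, 0.0)
    grad = (-2.0 / c) * (w.sum(axis=1)[:, None] * y - w @ y)
    return stress, grad


def _sammon_step_direction(y: np.ndarray, d: np.ndarray, c: float):
    """Gradient and the classic second-order (diagonal-Hessian) step direction,
    grad / |hess| -- scale-free, unlike a raw gradient step."""
    delta = squareform(pdist(y))
    np.fill_diagonal(delta, 1.0)
    dm = d.copy()
    np.fill_diagonal(dm, 1.0)
    diff = dm - delta
    iu = np.triu_indices_from(dm, k=1)
    stress = float((diff[iu] ** 2 / dm[iu]).sum() / c)
    w = diff / (dm * delta)
    np.fill_diagonal(w, 0.0)
    grad = (-2.0 / c) * (w.sum(axis=1)[:, None] * y - w @ y)
    # diagonal Hessian per coordinate
    inv = 1.0 / (dm * delta)
    np.fill_diagonal(inv, 0.0)
    corr = 1.0 + diff / delta
    np.fill_diagonal(corr, 0.0)
    n, k = y.shape
    hess = np.empty_like(y)
    for q in range(k):
        dy = y[:, q][:, None] - y[:, q][None, :]
        term = inv * (diff - (dy ** 2 / delta) * corr)
        np.fill_diagonal(term, 0.0)
        hess[:, q] = (-2.0 / c) * term.sum(axis=1)
    denom = np.maximum(np.abs(hess), 1e-12)
    return stress, grad, grad / denom


def sammon_map(t: FeatureTable, cfg: SammonState | None = None) -> tuple[np.ndarray, SammonState]:
    """Embed the table's rows into ``cfg.target_dim`` dimensions by minimising
    Sammon stress with gradient descent and step halving.

    Initialisation is the PCA projection, so the run is deterministic; the
    seed only matters when duplicate rows must be jittered apart.  The stress
    trace over accepted iterations is strictly non-increasing.
    """
    cfg = cfg or SammonState()
    x = t.values.astype(float)
    n = len(x)
    if n < 3:
        raise ValueError("Sammon mapping needs at least 3 rows")
    d = squareform(pdist(x))
    iu = np.triu_indices(n, k=1)
    mean_d = d[iu].mean()
    if mean_d == 0.0:
        raise ValueError("all rows identical; Sammon mapping undefined")
    if d[iu].min() <= 1e-12 * mean_d:
        # duplicate rows: nudge apart with a tiny seeded jitter
        rng = np.random.default_rng(cfg.seed)
        x = x + rng.normal(scale=1e-9 * mean_d, size=x.shape)
        d = squareform(pdist(x))
        cfg.jittered = True
        if d[iu].min() <= 0.0:
            raise ValueError("duplicate rows persist beyond jitter tolerance")
    c = float(d[iu].sum())

    # PCA initialisation (deterministic)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    k = cfg.target_dim
    y = np.zeros((n, k))
    m = min(k, len(s))
    y[:, :m] = u[:, :m] * s[:m]

    stress, _, direction = _sammon_step_direction(y, d, c)
    if not np.isfinite(stress):
        raise FloatingPointError("non-finite Sammon stress at initialisation")
    cfg.stress_trace = [stress]
    lr = cfg.learning_rate
    for it in range(cfg.max_iters):
        step = lr
        accepted = False
        for _ in range(30):  # step halving
            y_new = y - step * direction
            new_stress, _, new_direction = _sammon_step_direction(y_new, d, c)
            if np.isfinite(new_stress) and new_stress < stress:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (stress - new_stress) / max(stress, 1e-300)
        y, stress, direction = y_new, new_stress, new_direction
        cfg.stress_trace.append(stress)
        if not np.isfinite(stress):
            raise FloatingPointError(f"non-finite Sammon stress at iteration {it}")
        if rel < cfg.rel_tol:
            break
    return y, cfg


def sammon_table(t: FeatureTable, cfg: SammonState | None = None) -> FeatureTable:
    """Sammon embedding packaged as a FeatureTable (columns SD1..SDk)."""
    y, cfg = sammon_map(t, cfg)
    cols = [f"SD{j + 1}" for j in range(y.shape[1])]
    df = pd.DataFrame(y, index=t.df.index, columns=cols)
    return FeatureTable(df, {c: "other" for c in cols},
                        dict(t.labels) if t.labels else None)
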