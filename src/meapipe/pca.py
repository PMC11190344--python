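"""Parameter-vector assembly, per-timepoint standardization, PCA, and
Mahalanobis/Hotelling genotype-cluster separation.

Each well at each timepoint is summarized by a parameter vector built from
the well-metrics table (rates and durations log10-transformed). Vectors are
z-scored per timepoint (so the systematic developmental increase in
activity is removed), reduced by correlation PCA, and the two genotype
clouds are compared in the PC1-PC2 plane:

    D^2 = (mu_a - mu_b)' S_pooled^{-1} (mu_a - mu_b)
    T^2 = n_a n_b / (n_a + n_b) * D^2
    F   = (n_a + n_b - p - 1) / ((n_a + n_b - 2) p) * T^2,
          F ~ F(p, n_a + n_b - p - 1) under the null.

The per-feature PC1 projections (spiking / bursting / network bursting
presets) are sign-aligned so that higher activity maps to positive PC1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "ParameterVectorSpec",
    "PRESETS",
    "ClusterSeparation",
    "PCAResult",
    "build_vectors",
    "standardize_by_timepoint",
    "pca_fit",
    "cluster_separation",
    "feature_pc1_projection",
]

Transform = Literal["identity", "log10"]


@dataclass(frozen=True)
class ParameterVectorSpec:
    """Ordered (parameter name, transform) list defining a feature vector."""

    name: str
    entries: tuple[tuple[str, Transform], ...]
    # parameter whose loading fixes the PC1 sign ("higher activity" axis)
    activity_anchor: str = ""

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in vector spec")

    @property
    def columns(self) -> list[str]:
        return [n for n, _ in self.entries]


def _spec(name, entries, anchor):
    return ParameterVectorSpec(name, tuple(entries), anchor)


#: Printed feature presets plus the reconstructed 19-parameter vector.
#: The exact 19-parameter list of the original study is not public; this
#: default covers every well-level parameter the pipeline computes and is
#: fully configurable.
PRESETS: dict[str, ParameterVectorSpec] = {
    "spiking_4": _spec(
        "spiking_4",
        [("n_active_electrodes", "identity"), ("wmfr_hz", "log10"),
         ("wtmfr_hz", "log10"), ("mean_isi_s", "log10")],
        anchor="wmfr_hz",
    ),
    "bursting_3": _spec(
        "bursting_3",
        [("wmbr_hz", "log10"), ("mean_burst_duration_s", "log10"),
         ("mean_spikes_per_burst", "log10")],
        anchor="wmbr_hz",
    ),
    "network_4": _spec(
        "network_4",
        [("n_network_bursts", "identity"), ("mean_nb_duration_s", "identity"),
         ("mean_spikes_per_nb", "identity"), ("mean_channels_per_nb", "identity")],
        anchor="n_network_bursts",
    ),
    "full_19": _spec(
        "full_19",
        [("n_active_electrodes", "identity"), ("mfr_hz", "log10"),
         ("wmfr_hz", "log10"), ("wtmfr_hz", "log10"), ("mean_isi_s", "log10"),
         ("mbr_hz", "log10"), ("wmbr_hz", "log10"),
         ("mean_burst_duration_s", "log10"), ("mean_spikes_per_burst", "log10"),
         ("pct_spikes_in_bursts", "identity"), ("n_network_bursts", "identity"),
         ("mean_nb_duration_s", "log10"), ("mean_spikes_per_nb", "log10"),
         ("mean_channels_per_nb", "identity"), ("nb_rate_hz", "log10"),
         ("mean_sttc", "identity"), ("skewness_sttc", "identity"),
         ("pct_spikes_in_nbs", "identity"), ("mean_inter_nb_interval_s", "log10")],
        anchor="wmfr_hz",
    ),
}


def build_vectors(well_metrics: pd.DataFrame, spec: ParameterVectorSpec) -> pd.DataFrame:
    """Assemble the wells x parameters matrix for one timepoint.

    ``well_metrics`` is indexed by well (or has a ``well`` column) with one
    row per well. Transforms are applied; log10 of a non-positive value
    yields NaN so the completeness rule can exclude the well.
    """
    df = well_metrics.set_index("well") if "well" in well_metrics.columns else well_metrics
    missing = [n for n in spec.columns if n not in df.columns]
    if missing:
        raise KeyError(f"vector spec {spec.name!r} references unknown parameters: {missing}")
    out = {}
    for name, transform in spec.entries:
        col = df[name].astype(float)
        if transform == "log10":
            with np.errstate(divide="ignore", invalid="ignore"):
                col = pd.Series(np.where(col > 0, np.log10(np.abs(col.to_numpy()) + 1e-300),
                                         np.nan), index=col.index)
        out[name] = col
    return pd.DataFrame(out, index=df.index)[spec.columns]


def standardize_by_timepoint(
    matrix: pd.DataFrame,
    timepoint: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each column (sample SD, ddof=1) within each timepoint.

    With ``timepoint=None`` the whole matrix is one timepoint. Columns with
    zero variance in any timepoint are dropped with a warning; the list of
    dropped columns is returned for the provenance record.
    """
    if timepoint is None:
        groups = [(None, matrix)]
    else:
        groups = list(matrix.groupby(timepoint.reindex(matrix.index)))
    dropped: set[str] = set()
    pieces = []
    for _, grp in groups:
        if len(grp) < 2:
            raise ValueError("need >= 2 wells per timepoint to standardize")
        sd = grp.std(ddof=1)
        dropped |= set(sd.index[(sd == 0) | sd.isna()])
        pieces.append((grp - grp.mean()) / sd)
    z = pd.concat(pieces).reindex(matrix.index)
    if dropped:
        warnings.warn(f"zero-variance columns dropped before PCA: {sorted(dropped)}")
        z = z.drop(columns=sorted(dropped))
    return z, sorted(dropped)


@dataclass
class PCAResult:
    scores: pd.DataFrame         # wells x PCs ("PC1", "PC2", ...)
    loadings: pd.DataFrame       # parameters x PCs
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray


def pca_fit(z_matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Covariance-eigendecomposition PCA of the z-scored matrix.

    Components are ordered by decreasing eigenvalue; the sign convention
    makes the largest-magnitude loading coefficient of each component
    positive, so results are deterministic across library versions.
    """
    if z_matrix.isna().any().any():
        raise ValueError(
            "missing values in PCA input; apply the completeness filter first"
        )
    X = z_matrix.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    k = min(X.shape) if n_components is None else n_components
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # parameters x PCs
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    evr = model.explained_variance_ratio_
    # with k = min(n, p) components on centered data the ratios sum to 1
    return PCAResult(
        scores=pd.DataFrame(scores, index=z_matrix.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=z_matrix.columns, columns=pcs),
        explained_variance_ratio=np.asarray(evr),
        mean_=model.mean_,
    )


@dataclass(frozen=True)
class ClusterSeparation:
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    mahalanobis_d: float
    hotelling_t2: float
    f_value: float
    dof: tuple[int, int]
    p_value: float
    n_a: int
    n_b: int
    label_a: str = "a"
    label_b: str = "b"


def cluster_separation(
    scores: pd.DataFrame | np.ndarray,
    labels: Sequence,
    ridge: float = 0.0,
) -> ClusterSeparation:
    """Mahalanobis / Hotelling two-sample separation of two groups of scores.

    ``scores`` are points in the (typically PC1-PC2) plane; ``labels`` must
    take exactly two values, each with at least p+1 points. The pooled
    within-group covariance uses the n_a + n_b - 2 denominator. A singular
    pooled covariance raises unless a ``ridge`` epsilon is supplied.
    """
    X = np.asarray(scores, float)
    lab = np.asarray(labels)
    groups = sorted(pd.unique(lab).tolist())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a, b = (X[lab == g] for g in groups)
    p = X.shape[1]
    n_a, n_b = len(a), len(b)
    if n_a < p + 1 or n_b < p + 1:
        raise ValueError(f"each group needs >= p+1 = {p + 1} points")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    s_pooled = (
        (n_a - 1) * np.cov(a, rowvar=False, ddof=1)
        + (n_b - 1) * np.cov(b, rowvar=False, ddof=1)
    ) / (n_a + n_b - 2)
    s_pooled = np.atleast_2d(s_pooled) + ridge * np.eye(p)
    diff = mu_a - mu_b
    try:
        sol = np.linalg.solve(s_pooled, diff)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; pass a small ridge epsilon"
        ) from err
    d2 = float(diff @ sol)
    t2 = n_a * n_b / (n_a + n_b) * d2
    n = n_a + n_b
    f_val = (n - p - 1) / ((n - 2) * p) * t2
    dof = (p, n - p - 1)
    p_value = float(sps.f.sf(f_val, *dof))
    return ClusterSeparation(
        centroid_a=mu_a,
        centroid_b=mu_b,
        mahalanobis_d=math.sqrt(max(d2, 0.0)),
        hotelling_t2=t2,
        f_value=f_val,
        dof=dof,
        p_value=p_value,
        n_a=n_a,
        n_b=n_b,
        label_a=str(groups[0]),
        label_b=str(groups[1]),
    )


def feature_pc1_projection(
    well_metrics_table: pd.DataFrame,
    preset: ParameterVectorSpec | str,
    cohort_col: str = "cohort",
    min_wells: int = 3,
) -> pd.DataFrame:
    """Per-cohort PC1 scores of a feature preset (spiking_4 / bursting_3 /
    network_4), sign-aligned so that higher activity is positive.

    ``well_metrics_table`` is long-form with columns ``well``, ``cohort_col``
    and the preset parameters; wells with a missing transformed value in a
    cohort are excluded from that cohort. Cohorts with fewer than
    ``min_wells`` complete wells are skipped with a warning.
    """
    spec = PRESETS[preset] if isinstance(preset, str) else preset
    rows = []
    for cohort, grp in well_metrics_table.groupby(cohort_col):
        vec = build_vectors(grp.set_index("well"), spec).dropna()
        if len(vec) < min_wells:
            warnings.warn(f"cohort {cohort}: fewer than {min_wells} complete wells, skipped")
            continue
        z, dropped = standardize_by_timepoint(vec)
        if z.shape[1] == 0:
            warnings.warn(f"cohort {cohort}: all columns degenerate, skipped")
            continue
        res = pca_fit(z)
        pc1 = res.scores["PC1"].copy()
        anchor = spec.activity_anchor
        if anchor in res.loadings.index and res.loadings.loc[anchor, "PC1"] < 0:
            pc1 = -pc1
        for well, val in pc1.items():
            rows.append({"well": well, cohort_col: cohort, "pc1": float(val)})
    return pd.DataFrame(rows, columns=["well", cohort_col, "pc1"])
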