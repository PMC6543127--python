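"""LC-MS peak-area chemometrics.

Peak areas are total-normalised to 1,000,000 per sample. Class
discrimination uses partial least squares (NIPALS PLS1 on autoscaled data
with a centred +/-1 response) and its orthogonal variant (Trygg-Wold
O-PLS), with feature relevance summarised by VIP (variable importance in
projection). Differential metabolites satisfy VIP > 1 and Welch-t p < 0.05;
compounds measured in both ionisation modes keep the lower-p mode, and
serum/feces concordance is assessed on the sign of log2 fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeakTable, group_masks

__all__ = [
    "normalize_total",
    "plsda_fit",
    "vip_scores",
    "oplsda_fit",
    "differential_metabolites",
    "merge_modes",
    "cross_compartment",
    "PLSModel",
]

TOTAL = 1_000_000.0


def normalize_total(peaks: PeakTable, total: float = TOTAL) -> PeakTable:
    """Scale each sample's areas to sum to ``total`` (default 1,000,000)."""
    sums = peaks.areas.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[int(np.argmax((sums <= 0).to_numpy()))]
        raise ValueError(f"sample {bad!r} has zero total peak area")
    areas = peaks.areas / sums * total
    return PeakTable(meta=peaks.meta, areas=areas, normalized=True)


@dataclass
class PLSModel:
    """NIPALS PLS1 / O-PLS model on autoscaled X and centred +/-1 y."""

    weights: np.ndarray          # A x p, unit-norm rows
    scores: np.ndarray           # n x A
    x_loadings: np.ndarray       # A x p
    y_loadings: np.ndarray       # A
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    feature_ids: list[str]
    ortho_weights: np.ndarray | None = None
    ortho_scores: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]


def _autoscale(X: np.ndarray, scale: bool = True):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    keep = sd > 0
    return mu, np.where(keep, sd, 1.0), keep


def _prepare(X: pd.DataFrame, y, scale: bool):
    Xv = X.to_numpy(dtype=float)
    yb = np.asarray(y)
    levels = np.unique(yb)
    if len(levels) != 2:
        raise ValueError("PLS-DA needs exactly two classes")
    positive = "case" if "case" in levels else levels[1]
    yv = np.where(yb == positive, 1.0, -1.0)
    for lv in levels:
        if (yb == lv).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    mu, sd, keep = _autoscale(Xv, scale)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)")
    Xc = (Xv[:, keep] - mu[keep]) / sd[keep]
    y_mean = yv.mean()
    return Xc, yv - y_mean, mu[keep], sd[keep], y_mean, list(np.array(X.columns)[keep])


def plsda_fit(X: pd.DataFrame, y, n_components: int = 2,
              scale: bool = True) -> PLSModel:
    """NIPALS PLS1 discriminant model.

    X is column-wise mean-centred and unit-variance scaled; the response is
    the centred +/-1 class code. With a single response, each component's
    weight vector has the closed form w = X'y / ||X'y||; X is deflated by
    t p' after each component.
    """
    Xc, yc, mu, sd, y_mean, feats = _prepare(X, y, scale)
    A = int(n_components)
    if A < 1 or A > min(Xc.shape):
        raise ValueError(f"n_components must be in 1..{min(Xc.shape)}")
    W, T, P, Q = [], [], [], []
    Xd = Xc.copy()
    for _ in range(A):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError("response carries no covariance with X")
        w /= norm
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = yc @ t / tt
        Xd -= np.outer(t, p)
        W.append(w)
        T.append(t)
        P.append(p)
        Q.append(q)
    return PLSModel(
        weights=np.array(W),
        scores=np.array(T).T,
        x_loadings=np.array(P),
        y_loadings=np.array(Q),
        x_mean=mu,
        x_scale=sd,
        y_mean=y_mean,
        feature_ids=feats,
    )


def vip_scores(model: PLSModel) -> pd.Series:
    """VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ), SS_a = q_a^2 t_a't_a.

    The mean of VIP^2 over features equals 1 by construction.
    """
    W = model.weights
    T = model.scores
    Q = model.y_loadings
    p = W.shape[1]
    ss = Q ** 2 * (T ** 2).sum(axis=0)
    if ss.sum() <= 0:
        raise ValueError("zero explained response variance")
    vip = np.sqrt(p * (ss[:, None] * W ** 2).sum(axis=0) / ss.sum())
    return pd.Series(vip, index=model.feature_ids)


def oplsda_fit(X: pd.DataFrame, y, n_orthogonal: int = 1,
               scale: bool = True) -> PLSModel:
    """Trygg-Wold O-PLS: strip response-orthogonal variation, then one
    predictive PLS1 component.

    Each orthogonal component's weight is the part of the X-loading
    orthogonal to the predictive weight; its scores are uncorrelated with
    the response by construction.
    """
    Xc, yc, mu, sd, y_mean, feats = _prepare(X, y, scale)
    if n_orthogonal < 0 or n_orthogonal >= min(Xc.shape):
        raise ValueError("n_orthogonal must be in 0..rank(X)-1")
    Xd = Xc.copy()
    Wo, To, Po = [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        Wo.append(w_o)
        To.append(t_o)
        Po.append(p_o)
    # final predictive component on the deflated matrix
    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    t = Xd @ w
    tt = t @ t
    p = Xd.T @ t / tt
    q = yc @ t / tt
    return PLSModel(
        weights=w[None, :],
        scores=t[:, None],
        x_loadings=p[None, :],
        y_loadings=np.array([q]),
        x_mean=mu,
        x_scale=sd,
        y_mean=y_mean,
        feature_ids=feats,
        ortho_weights=np.array(Wo) if Wo else np.empty((0, len(feats))),
        ortho_scores=np.array(To).T if To else np.empty((Xc.shape[0], 0)),
        ortho_loadings=np.array(Po) if Po else np.empty((0, len(feats))),
    )


def differential_metabolites(
    peaks: PeakTable,
    meta: pd.DataFrame,
    n_components: int = 2,
    vip_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """VIP (PLS-DA) + Welch-t differential table for one peak table.

    ``selected`` requires VIP > ``vip_cutoff`` AND p < ``p_cutoff``; fold
    change is mean(case)/mean(control) of normalised areas.
    """
    if not peaks.normalized:
        peaks = normalize_total(peaks)
    case_mask, control_mask = group_masks(meta, peaks.sample_ids, case, control)
    X = peaks.areas.T  # samples x features
    y = meta.loc[peaks.sample_ids, "group"]
    model = plsda_fit(X, y, n_components=n_components)
    vip = vip_scores(model).reindex(peaks.feature_ids)
    areas = peaks.areas.to_numpy()
    tstat, pvals = stats.ttest_ind(
        areas[:, case_mask], areas[:, control_mask], axis=1, equal_var=False
    )
    mean_case = areas[:, case_mask].mean(axis=1)
    mean_control = areas[:, control_mask].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_control
        log2fc = np.log2(fc)
    out = peaks.meta.copy()
    out["VIP"] = vip.to_numpy()
    out["t"] = tstat
    out["p"] = pvals
    out["mean_case"] = mean_case
    out["mean_control"] = mean_control
    out["FC"] = fc
    out["log2FC"] = log2fc
    out["selected"] = (out["VIP"] > vip_cutoff) & (out["p"] < p_cutoff)
    return out


def merge_modes(pos: pd.DataFrame, neg: pd.DataFrame) -> pd.DataFrame:
    """Merge ES+ and ES- differential tables; named compounds present in
    both modes keep the row with the lower p-value, everything else passes
    through."""
    frames = []
    for df in (pos, neg):
        named = df[df["compound"].astype(str) != ""]
        dup = named["compound"][named["compound"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate compound within one mode: {dup.iloc[0]!r}")
        frames.append(df)
    both = pd.concat(frames)
    unnamed = both[both["compound"].astype(str) == ""]
    named = both[both["compound"].astype(str) != ""]
    keep = named.sort_values(["compound", "p"], kind="mergesort") \
                .drop_duplicates("compound", keep="first")
    return pd.concat([keep, unnamed]).sort_index()


def cross_compartment(
    serum: pd.DataFrame, feces: pd.DataFrame
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Serum/feces concordance of selected compounds.

    ``shared`` = compound names selected in both compartments; ``concordant``
    = shared compounds whose log2 fold changes agree in sign. The heat
    matrix holds each compartment's log2FC standardised across the shared
    compounds (mean 0, SD 1 per compartment).
    """
    def selected_named(df):
        sel = df[df["selected"] & (df["compound"].astype(str) != "")]
        return sel.set_index("compound")

    s_sel = selected_named(serum)
    f_sel = selected_named(feces)
    shared = sorted(set(s_sel.index) & set(f_sel.index))
    concordant = [
        c for c in shared
        if np.sign(s_sel.loc[c, "log2FC"]) == np.sign(f_sel.loc[c, "log2FC"])
    ]
    heat = pd.DataFrame(
        {
            "serum": s_sel.loc[shared, "log2FC"],
            "feces": f_sel.loc[shared, "log2FC"],
        }
    )
    if len(shared) > 1:
        heat = (heat - heat.mean()) / heat.std(ddof=0)
    return shared, concordant, heat
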