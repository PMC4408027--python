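"""Normality-gated trait correlations and trait summaries.

The workflow mirrors common practice in comparative trait ecology:
species means are screened with the Shapiro-Wilk test, a pair of traits
is correlated with Pearson's r when both are approximately normal and
with Spearman's rho otherwise, and two-sided p values are banded at
0.05 / 0.01 / 0.001.  No multiple-testing correction is applied — with
many simultaneous pairs the individual tests are descriptive and should
not be over-interpreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reference as ref
from .traits import nfold_variation

__all__ = [
    "NormalityResult",
    "CorrelationResult",
    "CorrelationMatrix",
    "shapiro_normal",
    "normality_screen",
    "correlate_pair",
    "correlation_matrix",
    "summarize_traits",
    "significance_band",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityResult:
    trait: str
    W: float
    p: float
    is_normal: bool


@dataclass(frozen=True)
class CorrelationResult:
    trait_x: str
    trait_y: str
    method: str           # "pearson" | "spearman"
    coefficient: float
    p: float
    n: int
    significance_band: str


@dataclass
class CorrelationMatrix:
    """Pearson, Spearman and the method-gated (headline) matrices.

    Every headline entry equals the corresponding Pearson entry when both
    traits are flagged normal and the Spearman entry otherwise.
    """

    traits: list[str]
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    headline: pd.DataFrame
    p_pearson: pd.DataFrame
    p_spearman: pd.DataFrame
    p_headline: pd.DataFrame
    method: pd.DataFrame
    n: pd.DataFrame
    normality: dict[str, bool] = field(default_factory=dict)

    def result(self, x: str, y: str) -> CorrelationResult:
        return CorrelationResult(
            trait_x=x, trait_y=y,
            method=str(self.method.loc[x, y]),
            coefficient=float(self.headline.loc[x, y]),
            p=float(self.p_headline.loc[x, y]),
            n=int(self.n.loc[x, y]),
            significance_band=significance_band(float(self.p_headline.loc[x, y])),
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, x in enumerate(self.traits):
            for y in self.traits[i + 1:]:
                r = self.result(x, y)
                rows.append({
                    "trait_x": x, "trait_y": y, "method": r.method,
                    "coefficient": r.coefficient, "p": r.p, "n": r.n,
                    "significance": r.significance_band,
                    "pearson": float(self.pearson.loc[x, y]),
                    "spearman": float(self.spearman.loc[x, y]),
                })
        return pd.DataFrame(rows)


def significance_band(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def shapiro_normal(values, trait: str = "", alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk test; a trait is treated as normal when p > alpha."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("constant values: normality is undefined")
    w, p = sps.shapiro(v)
    return NormalityResult(trait=trait, W=float(w), p=float(p), is_normal=bool(p > alpha))


def normality_screen(
    table: pd.DataFrame,
    traits=None,
    alpha: float = ALPHA,
    log10_traits: tuple[str, ...] = (),
) -> dict[str, NormalityResult]:
    """Shapiro-Wilk per trait on a species-level table.

    ``log10_traits`` are tested after a base-10 log transform (zeros
    dropped), the conventional variance-stabilizer for right-skewed
    traits such as vessel number per area or stiffness.
    """
    traits = list(traits) if traits is not None else [
        c for c in table.columns if c in ref.TRAIT_ORDER
    ]
    out: dict[str, NormalityResult] = {}
    for t in traits:
        v = table[t].to_numpy(dtype=float)
        if t in log10_traits:
            v = np.log10(v[v > 0])
        fin = v[np.isfinite(v)]
        if fin.size < 3 or np.ptp(fin) == 0:
            warnings.warn(
                f"trait {t} is constant or too short for a normality test; skipped",
                stacklevel=2,
            )
            continue
        out[t] = shapiro_normal(v, trait=t, alpha=alpha)
    return out


def correlate_pair(
    x, y, normal_x: bool, normal_y: bool, trait_x: str = "x", trait_y: str = "y"
) -> CorrelationResult:
    """Pearson when both traits are normal, Spearman otherwise; two-sided p.

    Missing values are removed pairwise; zero variance after deletion is
    an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if normal_x and normal_y:
        method = "pearson"
        r, p = sps.pearsonr(x, y)
    else:
        method = "spearman"
        r, p = sps.spearmanr(x, y)
    return CorrelationResult(
        trait_x=trait_x, trait_y=trait_y, method=method,
        coefficient=float(r), p=float(p), n=int(x.size),
        significance_band=significance_band(float(p)),
    )


def correlation_matrix(
    table: pd.DataFrame,
    traits=None,
    normality: dict[str, bool] | None = None,
    alpha: float = ALPHA,
    site: str | None = None,
) -> CorrelationMatrix:
    """Full pairwise Pearson/Spearman/headline matrices on species means.

    ``normality`` maps trait -> bool; when omitted it is derived from a
    Shapiro-Wilk screen of the table itself.  ``site`` restricts the
    computation to one site's species.  Zero-variance traits are dropped
    with a warning.
    """
    if site is not None:
        table = table[table["site"] == site]
    traits = list(traits) if traits is not None else [
        c for c in table.columns if c in ref.TRAIT_ORDER
    ]
    if len(table) < 3:
        raise ValueError("need at least 3 species")
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    kept = []
    for t in traits:
        v = table[t].to_numpy(dtype=float)
        if np.ptp(v[np.isfinite(v)]) == 0:
            warnings.warn(f"trait {t} has zero variance and was dropped", stacklevel=2)
        else:
            kept.append(t)
    traits = kept
    if normality is None:
        normality = {
            t: res.is_normal for t, res in normality_screen(table, traits, alpha).items()
        }
    d = len(traits)
    mk = lambda: pd.DataFrame(np.eye(d), index=traits, columns=traits)
    pears, spear, head = mk(), mk(), mk()
    pp, ps, ph = mk() * 0.0, mk() * 0.0, mk() * 0.0
    method = pd.DataFrame("", index=traits, columns=traits)
    nmat = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    for i, x in enumerate(traits):
        nmat.loc[x, x] = int(np.isfinite(table[x].to_numpy(dtype=float)).sum())
        for y in traits[i + 1:]:
            both_normal = normality.get(x, False) and normality.get(y, False)
            xv = table[x].to_numpy(dtype=float)
            yv = table[y].to_numpy(dtype=float)
            keep = np.isfinite(xv) & np.isfinite(yv)
            rp, pvp = sps.pearsonr(xv[keep], yv[keep])
            rs, pvs = sps.spearmanr(xv[keep], yv[keep])
            pears.loc[x, y] = pears.loc[y, x] = rp
            spear.loc[x, y] = spear.loc[y, x] = rs
            pp.loc[x, y] = pp.loc[y, x] = pvp
            ps.loc[x, y] = ps.loc[y, x] = pvs
            head.loc[x, y] = head.loc[y, x] = rp if both_normal else rs
            ph.loc[x, y] = ph.loc[y, x] = pvp if both_normal else pvs
            method.loc[x, y] = method.loc[y, x] = (
                "pearson" if both_normal else "spearman"
            )
            nmat.loc[x, y] = nmat.loc[y, x] = int(keep.sum())
    return CorrelationMatrix(
        traits=traits, pearson=pears, spearman=spear, headline=head,
        p_pearson=pp, p_spearman=ps, p_headline=ph,
        method=method, n=nmat, normality=dict(normality),
    )


def summarize_traits(
    table: pd.DataFrame, traits=None, ndigits: dict[str, int] | None = None
) -> pd.DataFrame:
    """Species-level trait overview: low, high, average, n-fold variation.

    For traits that are exactly zero in some species (tissue absent) the
    low, average and n-fold use the species where the tissue is present,
    i.e. the lowest value different from zero; ``n_present`` reports how
    many species carry the tissue.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    traits = list(traits) if traits is not None else [
        c for c in table.columns if c in ref.TRAIT_ORDER
    ]
    rows = []
    for t in traits:
        v = table[t].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        pos = v[v > 0]
        if pos.size == 0:
            # tissue absent from every species: the overview row is all
            # zeros and the fold variation is undefined
            rows.append({
                "trait": t, "low": 0.0, "high": 0.0, "average": 0.0,
                "nfold": np.nan, "n_present": 0, "n": int(v.size),
            })
            continue
        rows.append({
            "trait": t,
            "low": pos.min(),
            "high": v.max(),
            "average": pos.mean(),
            "nfold": nfold_variation(v),
            "n_present": int(pos.size),
            "n": int(v.size),
        })
    out = pd.DataFrame(rows)
    if ndigits:
        for col in ("low", "high", "average", "nfold"):
            out[col] = [
                round(val, ndigits[t]) if t in ndigits else val
                for t, val in zip(out["trait"], out[col])
            ]
    return out
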