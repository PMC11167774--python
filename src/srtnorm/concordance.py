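"""Agreement between skewed-panel and full-panel results.

The full-panel run is treated as ground truth. Significance confusion gives
false positive/negative rates; fold-change sign confusion gives switched
positive/negative rates; scaling factors are compared by RMSE after
unit-mean rescaling; normalized magnitudes by per-gene Pearson correlation.
Rates with a zero denominator are reported as ``None`` (undefined), never 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NormalizedMatrix
from .de import LFC_OK, bh_adjust
from .normalization import ScalingFactors, rescale_unit_mean


@dataclass
class ConfusionCounts:
    """Significance (FP/FN/TP/TN) and sign (SP/SN) confusion tallies."""

    FP: int = 0
    FN: int = 0
    TP: int = 0
    TN: int = 0
    SP: int = 0
    SN: int = 0
    TP_sign: int = 0
    TN_sign: int = 0


def _rate(num: int, denom: int) -> float | None:
    return None if denom == 0 else num / denom


def _match(skewed: pd.DataFrame, full: pd.DataFrame) -> pd.DataFrame:
    merged = skewed.merge(full, on=["gene", "region"], suffixes=("_skew", "_full"),
                          how="inner", validate="one_to_one")
    if merged.empty:
        raise ValueError("no (gene, region) tests shared between the two runs")
    return merged


def de_error_rates(skewed: pd.DataFrame, full: pd.DataFrame,
                   alpha: float = 0.05, readjust: bool = True
                   ) -> tuple[float | None, float | None, ConfusionCounts]:
    """FPR = FP/(FP+TN), FNR = FN/(FN+TP) with the full panel as truth.

    With ``readjust`` (default) the adjusted p-values of both runs are
    recomputed per region over the matched gene family, so that a panel run
    and a full run with identical raw p-values (e.g. volume normalization or
    no normalization) are scored as identical instead of being penalized for
    their different multiple-testing family sizes.
    """
    m = _match(skewed, full)
    if readjust:
        for col in ("p_skew", "p_full"):
            m[col.replace("p_", "p_adj_")] = (
                m.groupby("region", group_keys=False)[col]
                 .transform(lambda p: bh_adjust(p.to_numpy())))
    sig_s = m["p_adj_skew"].to_numpy() < alpha
    sig_f = m["p_adj_full"].to_numpy() < alpha
    cc = ConfusionCounts(
        FP=int(np.sum(sig_s & ~sig_f)),
        FN=int(np.sum(~sig_s & sig_f)),
        TP=int(np.sum(sig_s & sig_f)),
        TN=int(np.sum(~sig_s & ~sig_f)),
    )
    return _rate(cc.FP, cc.FP + cc.TN), _rate(cc.FN, cc.FN + cc.TP), cc


def fc_switch_rates(skewed: pd.DataFrame, full: pd.DataFrame
                    ) -> tuple[float | None, float | None, ConfusionCounts]:
    """SPR = SP/(SP+TN_sign), SNR = SN/(SN+TP_sign); zero LFC counts as nonpositive.

    Comparisons with undefined or infinite LFC in either run are excluded.
    """
    m = _match(skewed, full)
    ok = (m["lfc_flag_skew"] == LFC_OK) & (m["lfc_flag_full"] == LFC_OK)
    m = m[ok]
    pos_s = m["lfc_skew"].to_numpy() > 0
    pos_f = m["lfc_full"].to_numpy() > 0
    cc = ConfusionCounts(
        SP=int(np.sum(pos_s & ~pos_f)),
        SN=int(np.sum(~pos_s & pos_f)),
        TP_sign=int(np.sum(pos_s & pos_f)),
        TN_sign=int(np.sum(~pos_s & ~pos_f)),
    )
    return _rate(cc.SP, cc.SP + cc.TN_sign), _rate(cc.SN, cc.SN + cc.TP_sign), cc


def scaling_factor_rmse(sf_skewed: ScalingFactors, sf_full: ScalingFactors,
                        scale: str = "unit_mean") -> float:
    """RMSE over cells between factor vectors, unit-mean rescaled by default."""
    if list(sf_skewed.cell_ids) != list(sf_full.cell_ids):
        if set(sf_skewed.cell_ids) != set(sf_full.cell_ids):
            raise ValueError("factor vectors cover different cells")
        order = {c: i for i, c in enumerate(sf_full.cell_ids)}
        idx = np.argsort([order[c] for c in sf_skewed.cell_ids])
        sf_skewed = ScalingFactors([sf_skewed.cell_ids[i] for i in idx],
                                   sf_skewed.factors[idx], sf_skewed.method,
                                   sf_skewed.rescale)
    a = sf_skewed.factors
    b = sf_full.factors
    if scale == "unit_mean":
        a = rescale_unit_mean(sf_skewed).factors
        b = rescale_unit_mean(sf_full).factors
    elif scale != "none":
        raise ValueError("scale must be 'unit_mean' or 'none'")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def per_gene_correlation(norm_skewed: NormalizedMatrix,
                         norm_full: NormalizedMatrix) -> pd.Series:
    """Pearson r per shared gene across cells; NaN flags zero-variance genes.

    Identical value vectors short-circuit to exactly 1.0, so panel-invariant
    normalizations report perfect correlation without float fuzz.
    """
    shared = [g for g in norm_skewed.gene_ids if g in set(norm_full.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between the two runs")
    if list(norm_skewed.cell_ids) != list(norm_full.cell_ids):
        raise ValueError("runs must cover the same retained cells in the same order")
    if norm_skewed.n_cells < 2:
        raise ValueError("need at least two cells for correlation")
    a = norm_skewed.values[norm_skewed.gene_index(shared), :]
    b = norm_full.values[norm_full.gene_index(shared), :]
    out = np.empty(len(shared))
    for i in range(len(shared)):
        if np.array_equal(a[i], b[i]):
            out[i] = 1.0 if np.std(a[i]) > 0 else np.nan
        elif np.std(a[i]) == 0 or np.std(b[i]) == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(a[i], b[i])[0, 1]
    return pd.Series(out, index=shared, name="pearson_r")


@dataclass
class ConcordanceReport:
    """All agreement metrics for one (panel, method) pair vs the full panel."""

    panel: str
    method: str
    fpr: float | None = None
    fnr: float | None = None
    spr: float | None = None
    snr: float | None = None
    sf_rmse: float | None = None
    per_gene_r: pd.Series | None = field(default=None, repr=False)
    confusion: ConfusionCounts | None = None

    def to_rows(self) -> pd.DataFrame:
        rows = [
            {"panel": self.panel, "method": self.method, "metric": k,
             "value": v if v is not None else np.nan, "defined": v is not None}
            for k, v in [("fpr", self.fpr), ("fnr", self.fnr),
                         ("spr", self.spr), ("snr", self.snr),
                         ("sf_rmse", self.sf_rmse)]
        ]
        if self.per_gene_r is not None:
            defined = self.per_gene_r.dropna()
            rows.append({"panel": self.panel, "method": self.method,
                         "metric": "median_gene_r",
                         "value": float(defined.median()) if len(defined) else np.nan,
                         "defined": bool(len(defined))})
        return pd.DataFrame(rows)


def build_report(panel: str, method: str,
                 de_skewed: pd.DataFrame, de_full: pd.DataFrame,
                 sf_skewed: ScalingFactors | None, sf_full: ScalingFactors | None,
                 norm_skewed: NormalizedMatrix | None = None,
                 norm_full: NormalizedMatrix | None = None,
                 alpha: float = 0.05) -> ConcordanceReport:
    fpr, fnr, cc = de_error_rates(de_skewed, de_full, alpha=alpha)
    spr, snr, cc_sign = fc_switch_rates(de_skewed, de_full)
    cc.SP, cc.SN = cc_sign.SP, cc_sign.SN
    cc.TP_sign, cc.TN_sign = cc_sign.TP_sign, cc_sign.TN_sign
    rmse = None
    if sf_skewed is not None and sf_full is not None:
        rmse = scaling_factor_rmse(sf_skewed, sf_full)
    r = None
    if norm_skewed is not None and norm_full is not None:
        r = per_gene_correlation(norm_skewed, norm_full)
    return ConcordanceReport(panel=panel, method=method, fpr=fpr, fnr=fnr,
                             spr=spr, snr=snr, sf_rmse=rmse, per_gene_r=r,
                             confusion=cc)
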