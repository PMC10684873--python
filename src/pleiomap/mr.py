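"""Two-sample Mendelian randomization with sensitivity analyses.

Instruments are genome-wide significant SNPs for the exposure, clumped by
distance (and LD r-squared when a reference table is supplied), harmonized
to the outcome study's effect alleles, optionally Steiger-filtered, and fed
to inverse-variance-weighted (IVW) regression through the origin, MR-Egger
(free pleiotropy intercept) and the weighted median of Wald ratios.
Cochran's Q quantifies instrument heterogeneity; when Q exceeds its
expectation the IVW standard error is inflated multiplicatively
(random-effects). The per-region panel runs the full stack in either causal
direction with BH-FDR across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr, rng_stream

__all__ = [
    "HarmonizedInstruments",
    "MREstimate",
    "select_instruments",
    "region_power_filter",
    "harmonize",
    "ivw",
    "egger",
    "weighted_median",
    "steiger_filter",
    "mr_panel",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
SNP_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p")


def _validate_sumstats(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} summary table missing columns {missing}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{name} has non-positive standard errors")


@dataclass
class HarmonizedInstruments:
    table: pd.DataFrame  # snp_id, beta_exp, se_exp, beta_out, se_out, eaf
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    @property
    def n_snps(self) -> int:
        return len(self.table)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    Q: float | None = None
    Q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None


def select_instruments(
    exposure: pd.DataFrame,
    p_thresh: float = 5e-8,
    clump_kb: float = 10_000,
    clump_r2: float = 0.001,
    ld: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Greedy p-value clumping of genome-wide significant exposure SNPs.

    Repeatedly keeps the lowest-p SNP and removes same-chromosome SNPs
    within ``clump_kb`` kilobases whose LD r-squared with it exceeds
    ``clump_r2``; with no LD table, distance alone removes them. Returns an
    empty frame (not an error) if nothing survives.
    """
    _validate_sumstats(exposure, "exposure")
    cand = exposure.loc[exposure["p"] < p_thresh].sort_values("p").reset_index(drop=True)
    if cand.empty:
        return cand
    r2 = None
    if ld is not None:
        r2 = ld  # square DataFrame indexed by snp_id
    kept_rows = []
    remaining = cand.copy()
    while not remaining.empty:
        top = remaining.iloc[0]
        kept_rows.append(top)
        same_chr = remaining["chrom"] == top["chrom"]
        near = (remaining["pos"] - top["pos"]).abs() <= clump_kb * 1000
        in_window = same_chr & near
        if r2 is not None:
            linked = remaining["snp_id"].map(
                lambda s: float(r2.loc[top["snp_id"], s])
                if (top["snp_id"] in r2.index and s in r2.columns)
                else 1.0
            ) > clump_r2
            drop = in_window & linked
        else:
            drop = in_window
        drop.iloc[0] = True  # the kept SNP itself
        remaining = remaining.loc[~drop].reset_index(drop=True)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def region_power_filter(instrument_counts: dict[str, int], min_loci: int = 5) -> list[str]:
    """Regions with at least ``min_loci`` instruments (power criterion)."""
    return [r for r, c in instrument_counts.items() if c >= min_loci]


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    mode: str = "strict",
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstruments:
    """Align outcome effects to the exposure's effect alleles.

    Handles swapped alleles (sign flip), strand flips (complement alleles),
    and palindromic SNPs: under ``mode='strict'`` a palindromic SNP with
    effect-allele frequency inside ``palindromic_eaf_window`` is dropped as
    ambiguous. Irreconcilable allele pairs are dropped with a logged reason.
    """
    _validate_sumstats(exposure, "exposure")
    _validate_sumstats(outcome, "outcome")
    out_by_snp = outcome.set_index("snp_id")
    rows, excl = [], []
    for _, ex in exposure.iterrows():
        sid = ex["snp_id"]
        if sid not in out_by_snp.index:
            excl.append((sid, "absent from outcome"))
            continue
        ot = out_by_snp.loc[sid]
        ea_x, oa_x = str(ex["effect_allele"]), str(ex["other_allele"])
        ea_o, oa_o = str(ot["effect_allele"]), str(ot["other_allele"])
        beta_out, eaf_out = float(ot["beta"]), float(ot["eaf"])
        palindromic = _is_palindromic(ea_x, oa_x)
        if palindromic:
            lo, hi = palindromic_eaf_window
            if mode == "strict" and lo <= float(ex["eaf"]) <= hi:
                excl.append((sid, "palindromic with ambiguous frequency"))
                continue
            # infer orientation from allele frequency agreement
            if (ea_o, oa_o) in ((ea_x, oa_x), (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x])):
                same_freq_side = (float(ex["eaf"]) < 0.5) == (eaf_out < 0.5)
                if not same_freq_side:
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            else:
                excl.append((sid, "irreconcilable palindromic alleles"))
                continue
        else:
            if (ea_o, oa_o) == (ea_x, oa_x):
                pass
            elif (ea_o, oa_o) == (oa_x, ea_x):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            elif (ea_o, oa_o) == (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x]):
                pass  # strand flip, same orientation
            elif (ea_o, oa_o) == (_COMPLEMENT[oa_x], _COMPLEMENT[ea_x]):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            else:
                excl.append((sid, f"irreconcilable alleles {ea_x}/{oa_x} vs {ea_o}/{oa_o}"))
                continue
        rows.append(
            {
                "snp_id": sid,
                "beta_exp": float(ex["beta"]),
                "se_exp": float(ex["se"]),
                "beta_out": beta_out,
                "se_out": float(ot["se"]),
                "eaf": float(ex["eaf"]),
                "n_exp": int(ex["n"]) if "n" in ex else None,
                "n_out": int(ot["n"]) if "n" in ot else None,
            }
        )
    return HarmonizedInstruments(
        table=pd.DataFrame(rows, columns=["snp_id", "beta_exp", "se_exp", "beta_out",
                                          "se_out", "eaf", "n_exp", "n_out"]),
        exclusions=pd.DataFrame(excl, columns=["snp_id", "reason"]),
    )


def ivw(h: HarmonizedInstruments) -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of beta_out on beta_exp
    through the origin with weights 1/se_out^2.

    The standard error is inflated by sqrt(Q/(n-1)) when Cochran's Q exceeds
    its degrees of freedom (multiplicative random effects).
    """
    t = h.table
    n = len(t)
    if n < 2:
        raise ValueError("IVW needs at least 2 instruments")
    bx = t["beta_exp"].to_numpy()
    by = t["beta_out"].to_numpy()
    w = 1.0 / t["se_out"].to_numpy() ** 2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    se = float(np.sqrt(1.0 / np.sum(w * bx * bx)))
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    df = n - 1
    Q_p = float(stats.chi2.sf(Q, df))
    if Q / df > 1.0:
        se *= np.sqrt(Q / df)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate("IVW", beta, se, float(p), n, Q=Q, Q_p=Q_p)


def egger(h: HarmonizedInstruments) -> MREstimate:
    """MR-Egger: weighted regression with a free (pleiotropy) intercept.

    Instruments are oriented so beta_exp >= 0 before fitting; slope and
    intercept use t-inference on n-2 degrees of freedom.
    """
    t = h.table
    n = len(t)
    if n < 3:
        raise ValueError("Egger needs at least 3 instruments")
    sign = np.sign(t["beta_exp"].to_numpy())
    sign[sign == 0] = 1.0
    bx = t["beta_exp"].to_numpy() * sign
    by = t["beta_out"].to_numpy() * sign
    w = 1.0 / t["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones(n), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    df = n - 2
    sigma2 = max(float(np.sum(w * resid**2) / df), 1.0)  # multiplicative RE, floor 1
    cov = sigma2 * np.linalg.inv(XtWX)
    se_int, se_slope = np.sqrt(np.diag(cov))
    p_slope = 2.0 * stats.t.sf(abs(coef[1]) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(coef[0]) / se_int, df)
    Q = float(np.sum(w * resid**2))
    return MREstimate(
        "Egger", float(coef[1]), float(se_slope), float(p_slope), n,
        Q=Q, Q_p=float(stats.chi2.sf(Q, df)),
        egger_intercept=float(coef[0]), egger_intercept_p=float(p_int),
    )


def weighted_median(h: HarmonizedInstruments, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Weights are the inverse delta-method variances of the ratios; the SE
    comes from a parametric bootstrap over instrument effects.
    """
    t = h.table
    n = len(t)
    if n < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    bx = t["beta_exp"].to_numpy()
    by = t["beta_out"].to_numpy()
    sx = t["se_exp"].to_numpy()
    sy = t["se_out"].to_numpy()

    def _wm(bx_, by_):
        ratios = by_ / bx_
        var = sy**2 / bx_**2 + (by_**2) * (sx**2) / bx_**4
        w = 1.0 / var
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order]
        cw = np.cumsum(w_s) - 0.5 * w_s
        cw /= np.sum(w_s)
        return float(np.interp(0.5, cw, r_s))

    est = _wm(bx, by)
    rng = rng_stream(seed, "wm-boot")
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _wm(bx + rng.normal(scale=sx), by + rng.normal(scale=sy))
    se = float(boots.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 0.0
    return MREstimate("weighted-median", est, se, float(p), n)


def steiger_filter(
    h: HarmonizedInstruments,
    n_exp: int | None = None,
    n_out: int | None = None,
) -> HarmonizedInstruments:
    """Drop instruments that explain more outcome than exposure variance.

    Variance explained is approximated per SNP as z^2 / n. Sample sizes come
    from the harmonized table unless overridden; if unavailable the filter
    is skipped with a warning.
    """
    import warnings

    t = h.table
    ne = n_exp if n_exp is not None else (t["n_exp"].iloc[0] if t["n_exp"].notna().all() else None)
    no = n_out if n_out is not None else (t["n_out"].iloc[0] if t["n_out"].notna().all() else None)
    if ne is None or no is None:
        warnings.warn("sample sizes unavailable; Steiger filtering skipped")
        return h
    z_exp = (t["beta_exp"] / t["se_exp"]) ** 2 / float(ne)
    z_out = (t["beta_out"] / t["se_out"]) ** 2 / float(no)
    keep = z_exp.to_numpy() >= z_out.to_numpy()
    dropped = t.loc[~keep, "snp_id"]
    excl = pd.concat(
        [h.exclusions,
         pd.DataFrame({"snp_id": dropped, "reason": "Steiger: reverse causation"})],
        ignore_index=True,
    )
    return HarmonizedInstruments(table=t.loc[keep].reset_index(drop=True), exclusions=excl)


def mr_panel(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    p_thresh: float = 5e-8,
    min_loci: int = 5,
    fdr_q: float = 0.05,
    apply_steiger: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region MR in one causal direction with BH-FDR across regions.

    For each region's exposure table: select instruments, apply the power
    filter, harmonize against the outcome, optionally Steiger-filter, and
    fit IVW / Egger / weighted median. Sensitivity concordance flags sign
    agreement across the three estimators. Regions that fail are recorded
    with a status and skipped.
    """
    rows = []
    for region, exp_table in exposures.items():
        try:
            inst = select_instruments(exp_table, p_thresh=p_thresh)
            if len(inst) < min_loci:
                rows.append({"region_id": region, "status": "underpowered",
                             "n_snps": len(inst)})
                continue
            h = harmonize(inst, outcome)
            if apply_steiger:
                h = steiger_filter(h)
            if h.n_snps < min_loci:
                rows.append({"region_id": region, "status": "underpowered",
                             "n_snps": h.n_snps})
                continue
            est_ivw = ivw(h)
            est_egger = egger(h)
            est_wm = weighted_median(h, seed=seed)
            concordant = len({np.sign(e.beta) for e in (est_ivw, est_egger, est_wm)}) == 1
            rows.append(
                {
                    "region_id": region,
                    "status": "ok",
                    "n_snps": h.n_snps,
                    "beta_ivw": est_ivw.beta,
                    "se_ivw": est_ivw.se,
                    "p_ivw": est_ivw.p,
                    "Q": est_ivw.Q,
                    "Q_p": est_ivw.Q_p,
                    "beta_egger": est_egger.beta,
                    "egger_intercept": est_egger.egger_intercept,
                    "egger_intercept_p": est_egger.egger_intercept_p,
                    "beta_wm": est_wm.beta,
                    "sign_concordant": concordant,
                }
            )
        except (ValueError, KeyError) as e:
            rows.append({"region_id": region, "status": f"failed: {e}"})
    panel = pd.DataFrame(rows)
    ok = panel["status"] == "ok" if "status" in panel else pd.Series(dtype=bool)
    q = np.full(len(panel), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(panel.loc[ok, "p_ivw"].to_numpy())
    panel["q_ivw"] = q
    panel["significant"] = panel["q_ivw"] < fdr_q
    return panel
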