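"""Decision rules on the posterior draws: presence, high/low expression,
differential calls (Bayesian t plus indicator rule), and cross-condition
variability classes.

All percentile thresholds are nearest-rank with strict inequalities, shared
with the rest of the package; ties fall outside the extreme classes.  No
multiple-testing correction is applied anywhere: the extreme-decile rule (R2)
is itself a rank-based selection, and the remaining rules are posterior
probability statements rather than frequentist tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import nearest_rank_percentile
from .hierarchical_model import PosteriorSamples

log = logging.getLogger(__name__)

__all__ = [
    "isoform_summaries",
    "call_high_low",
    "bayesian_t",
    "differential_calls",
    "indicator_differential",
    "variability_classify",
    "pairwise_overlap_table",
    "gene_level_summary",
]


# ---------------------------------------------------------------------------
# Isoform-level posterior summaries
# ---------------------------------------------------------------------------


def isoform_summaries(fits: dict[str, PosteriorSamples] | list[PosteriorSamples]) -> pd.DataFrame:
    """One row per gene x isoform x sample: posterior presence probability,
    posterior mean/SD of beta* = I * beta, and PPI bounds at the 2.5/5/95/97.5
    posterior percentiles of beta*."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    rows = []
    for samples in fits:
        bstar = samples.pooled("beta_star")  # (draws, s, L)
        pres = samples.presence_prob()
        q = np.percentile(bstar, [2.5, 5, 95, 97.5], axis=0)  # (4, s, L)
        mean = bstar.mean(axis=0)
        sd = bstar.std(axis=0, ddof=1)
        for k, iso in enumerate(samples.isoform_ids):
            for l, sid in enumerate(samples.sample_ids):
                rows.append(
                    {
                        "gene_id": samples.gene_id,
                        "isoform_id": iso,
                        "sample_id": sid,
                        "presence_prob": float(pres[k, l]),
                        "expr_mean": float(mean[k, l]),
                        "expr_sd": float(sd[k, l]),
                        "ppi_2.5": float(q[0, k, l]),
                        "ppi_5": float(q[1, k, l]),
                        "ppi_95": float(q[2, k, l]),
                        "ppi_97.5": float(q[3, k, l]),
                        "n_segments": samples.n_segments,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# High / low expression calling
# ---------------------------------------------------------------------------


def call_high_low(summaries: pd.DataFrame) -> pd.DataFrame:
    """Label isoform x sample entries high / low / none.

    ``low``: the 95th PPI percentile of the isoform's expression falls below
    the 10th percentile of all posterior-mean expressions — with 95% posterior
    probability the isoform sits in the bottom 10% of expressions.  ``high``:
    the 5th PPI percentile exceeds the 90th percentile of the means.  The
    reference percentiles are nearest-rank over all isoform x sample means in
    the run.
    """
    n_iso = summaries[["gene_id", "isoform_id"]].drop_duplicates().shape[0]
    if n_iso < 2:
        raise ValueError("high/low reference percentiles need at least 2 isoforms")
    if n_iso < 10:
        log.warning("high/low calling with only %d isoforms; reference percentiles are coarse", n_iso)
    means = summaries["expr_mean"].to_numpy()
    ref_lo = nearest_rank_percentile(means, 10)
    ref_hi = nearest_rank_percentile(means, 90)
    out = summaries.copy()
    low = out["ppi_95"] < ref_lo
    high = out["ppi_5"] > ref_hi
    out["call"] = np.where(low, "low", np.where(high, "high", "none"))
    out.attrs["reference_percentiles"] = {"p10": ref_lo, "p90": ref_hi}
    return out


# ---------------------------------------------------------------------------
# Bayesian t and differential calls
# ---------------------------------------------------------------------------


@dataclass
class BayesianT:
    gene_id: str
    isoform_id: str
    pair: tuple[str, str]
    draws: np.ndarray  # posterior draws of the t-like contrast
    n_segments: int

    @property
    def t_mean(self) -> float:
        return float(self.draws.mean())

    def ppi(self, level: float = 0.95) -> tuple[float, float]:
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.draws, [a, 100 - a])
        return float(lo), float(hi)


def bayesian_t(samples: PosteriorSamples, isoform: str, pair: tuple[str, str]) -> BayesianT:
    """Posterior draws of the t-like contrast between two samples.

    Per draw,

        t = (beta*_k,l1 - beta*_k,l2) / sqrt(1/(m tau_l1) + 1/(m tau_l2)),

    a difference of isoform expressions over the root-sum of the two samples'
    per-segment noise variances averaged over the gene's ``m`` segments.  The
    statistic is antisymmetric in the pair and scale-invariant under common
    rescaling of numerator and denominator.
    """
    k = samples.isoform_ids.index(isoform)
    l1 = samples.sample_ids.index(pair[0])
    l2 = samples.sample_ids.index(pair[1])
    bstar = samples.pooled("beta_star")
    tau = samples.pooled("tau")
    m = samples.n_segments
    num = bstar[:, k, l1] - bstar[:, k, l2]
    den = np.sqrt(1.0 / (m * tau[:, l1]) + 1.0 / (m * tau[:, l2]))
    return BayesianT(samples.gene_id, isoform, pair, num / den, m)


def _verdict(sign: float, differential: bool) -> str:
    if not differential:
        return "none"
    return "up" if sign > 0 else "down"


def differential_calls(
    fits: dict[str, PosteriorSamples] | list[PosteriorSamples],
    pair: tuple[str, str],
    level: float = 0.95,
    decile: float = 10.0,
) -> pd.DataFrame:
    """Differential-expression calls for one sample pair, all isoforms.

    Three rules are emitted per isoform:

    * ``R1-ppi-zero``: differential iff the symmetric ``level`` PPI of t
      excludes zero.
    * ``R2-extreme-decile``: differential iff the PPI lies entirely in the
      upper or lower ``decile`` percent of all isoforms' posterior-mean t
      values (rank-based; usable for single-segment isoforms too).
    * ``R3-t-critical``: differential iff |posterior mean t| exceeds the
      two-sided 5% Student-t critical value with ``2(m-1)`` degrees of
      freedom; only defined for isoforms with two or more segments.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    stats_list: list[BayesianT] = []
    for samples in fits:
        if pair[0] not in samples.sample_ids or pair[1] not in samples.sample_ids:
            raise ValueError(f"gene {samples.gene_id} was not fitted with samples {pair}")
        for iso in samples.isoform_ids:
            stats_list.append(bayesian_t(samples, iso, pair))
    all_means = np.array([t.t_mean for t in stats_list])
    ref_lo = nearest_rank_percentile(all_means, decile)
    ref_hi = nearest_rank_percentile(all_means, 100 - decile)
    rows = []
    for t in stats_list:
        lo, hi = t.ppi(level)
        rows.append(
            {
                "gene_id": t.gene_id,
                "isoform_id": t.isoform_id,
                "sample_1": pair[0],
                "sample_2": pair[1],
                "rule": "R1-ppi-zero",
                "t_mean": t.t_mean,
                "ppi_lo": lo,
                "ppi_hi": hi,
                "n_segments": t.n_segments,
                "verdict": _verdict(t.t_mean, lo > 0 or hi < 0),
            }
        )
        r2_diff = lo > ref_hi or hi < ref_lo
        rows.append(
            {
                "gene_id": t.gene_id,
                "isoform_id": t.isoform_id,
                "sample_1": pair[0],
                "sample_2": pair[1],
                "rule": "R2-extreme-decile",
                "t_mean": t.t_mean,
                "ppi_lo": lo,
                "ppi_hi": hi,
                "n_segments": t.n_segments,
                "verdict": _verdict(1.0 if lo > ref_hi else -1.0, r2_diff),
            }
        )
        if t.n_segments >= 2:
            crit = stats.t.ppf(0.975, df=2 * (t.n_segments - 1))
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "isoform_id": t.isoform_id,
                    "sample_1": pair[0],
                    "sample_2": pair[1],
                    "rule": "R3-t-critical",
                    "t_mean": t.t_mean,
                    "ppi_lo": lo,
                    "ppi_hi": hi,
                    "n_segments": t.n_segments,
                    "verdict": _verdict(t.t_mean, abs(t.t_mean) > crit),
                }
            )
        else:
            log.info(
                "gene %s isoform %s: single segment, t-critical rule skipped",
                t.gene_id,
                t.isoform_id,
            )
    out = pd.DataFrame(rows)
    out.attrs["t_mean_percentiles"] = {"lo": ref_lo, "hi": ref_hi}
    return out


def indicator_differential(
    samples: PosteriorSamples, isoform: str, pair: tuple[str, str], conf: float = 0.95
) -> str:
    """Presence-indicator differential call, independent of expression amount.

    If the posterior presence probability is at least ``conf`` in one sample
    and at most ``1 - conf`` in the other, the isoform is declared
    differential in the direction of the expressed sample; otherwise none.
    This sidesteps the classical t-statistic's instability when one sample has
    zero counts.
    """
    k = samples.isoform_ids.index(isoform)
    l1 = samples.sample_ids.index(pair[0])
    l2 = samples.sample_ids.index(pair[1])
    pres = samples.presence_prob()
    p1, p2 = float(pres[k, l1]), float(pres[k, l2])
    if p1 >= conf and p2 <= 1 - conf:
        return "up"
    if p2 >= conf and p1 <= 1 - conf:
        return "down"
    return "none"


# ---------------------------------------------------------------------------
# Cross-condition variability
# ---------------------------------------------------------------------------


def variability_classify(
    fits: dict[str, PosteriorSamples] | list[PosteriorSamples],
    use: str = "variance",
    tail_prob: float = 0.05,
) -> dict:
    """Classify isoforms by cross-condition expression variability.

    The variability of isoform ``k`` is the posterior mean of ``1/tau0_k``
    (a variance; set ``use='precision'`` for ``tau0`` itself).  Classes use
    nearest-rank percentiles of the variability values over all isoforms with
    strict inequalities: ``low`` < 35th pct, ``moderate`` > 65th pct,
    ``high`` > 90th pct (high wins over moderate), else ``mid``.

    Also fits a Gamma distribution to the values by maximum likelihood, emits
    a QQ table against it, and reports the fraction of isoforms beyond the
    fitted Gamma's upper ``tail_prob`` tail — the screen for isoforms whose
    expression genuinely varies across conditions.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    rows = []
    for samples in fits:
        tau0 = samples.pooled("tau0")  # (draws, s)
        vals = (1.0 / tau0).mean(axis=0) if use == "variance" else tau0.mean(axis=0)
        for k, iso in enumerate(samples.isoform_ids):
            rows.append({"gene_id": samples.gene_id, "isoform_id": iso, "variability": float(vals[k])})
    table = pd.DataFrame(rows)
    if len(table) < 10:
        raise ValueError("variability classification needs at least 10 isoforms")
    v = table["variability"].to_numpy()
    t35 = nearest_rank_percentile(v, 35)
    t65 = nearest_rank_percentile(v, 65)
    t90 = nearest_rank_percentile(v, 90)
    cls = np.full(len(v), "mid", dtype=object)
    cls[v > t65] = "moderate"
    cls[v > t90] = "high"
    cls[v < t35] = "low"
    table["class"] = cls

    result = {
        "table": table,
        "thresholds": {"p35": t35, "p65": t65, "p90": t90},
        "gamma_fit": None,
        "qq": None,
        "tail_exceedance": None,
    }
    if np.ptp(v) == 0:
        log.warning("degenerate (constant) variabilities; Gamma fit skipped")
        return result
    shape, _, scale = stats.gamma.fit(v, floc=0)
    pcts = np.arange(5, 100, 5)
    observed = np.array([nearest_rank_percentile(v, p) for p in pcts])
    theoretical = stats.gamma.ppf(pcts / 100.0, shape, scale=scale)
    qq = pd.DataFrame({"percentile": pcts, "theoretical": theoretical, "observed": observed})
    cutoff = stats.gamma.ppf(1 - tail_prob, shape, scale=scale)
    result["gamma_fit"] = {"shape": float(shape), "scale": float(scale)}
    result["qq"] = qq
    result["tail_exceedance"] = float(np.mean(v > cutoff))
    return result


# ---------------------------------------------------------------------------
# Pairwise overlap of high/low lists
# ---------------------------------------------------------------------------


def pairwise_overlap_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Cross-condition overlap of high/low isoform lists.

    ``labels`` is the output of :func:`call_high_low`.  Returns a square table
    over conditions: upper triangle holds counts of commonly *high* isoforms
    for each pair, lower triangle commonly *low* ones; the extra ``total``
    column and row hold the per-condition list sizes (low and high
    respectively).
    """
    conditions = list(labels["sample_id"].drop_duplicates())
    if len(conditions) < 2:
        raise ValueError("need labels from at least 2 conditions")
    high_sets = {
        c: set(
            map(
                tuple,
                labels.query("sample_id == @c and call == 'high'")[["gene_id", "isoform_id"]].values,
            )
        )
        for c in conditions
    }
    low_sets = {
        c: set(
            map(
                tuple,
                labels.query("sample_id == @c and call == 'low'")[["gene_id", "isoform_id"]].values,
            )
        )
        for c in conditions
    }
    out = pd.DataFrame(
        0, index=pd.Index(conditions + ["total"], name="condition"), columns=conditions + ["total"],
        dtype=object,
    )
    for i, ci in enumerate(conditions):
        for j, cj in enumerate(conditions):
            if i < j:
                out.loc[ci, cj] = len(high_sets[ci] & high_sets[cj])
            elif i > j:
                out.loc[ci, cj] = len(low_sets[ci] & low_sets[cj])
            else:
                out.loc[ci, cj] = ""
        out.loc[ci, "total"] = len(low_sets[ci])
        out.loc["total", ci] = len(high_sets[ci])
    out.loc["total", "total"] = ""
    return out


# ---------------------------------------------------------------------------
# Gene-level expression
# ---------------------------------------------------------------------------


def gene_level_summary(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Posterior summary of total gene expression per sample: the draw-wise
    sum of beta* over isoforms."""
    bstar = samples.pooled("beta_star")  # (draws, s, L)
    total = bstar.sum(axis=1)  # (draws, L)
    a = 100 * (1 - level) / 2
    lo, hi = np.percentile(total, [a, 100 - a], axis=0)
    return pd.DataFrame(
        {
            "gene_id": samples.gene_id,
            "sample_id": samples.sample_ids,
            "expr_mean": total.mean(axis=0),
            "expr_sd": total.std(axis=0, ddof=1),
            "ppi_lo": lo,
            "ppi_hi": hi,
        }
    )
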