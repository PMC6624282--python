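"""Model comparison by BPIC and posterior-predictive defective CDFs.

BPIC (Bayesian Predictive Information Criterion) balances fit and
flexibility for hierarchically estimated models:

    D-bar  = mean posterior deviance, E[-2 log L]
    pD     = D-bar - D(theta-bar)   (deviance at the posterior mean)
    BPIC   = D-bar + 2 pD

Lower is better; the winning model has delta-BPIC = 0.  Per-sample data
log-likelihoods are stored during fitting, so D-bar is exact and cheap; a
minimum-deviance pD variant (D-bar - min D) is available behind a flag.

Posterior-predictive checks simulate datasets from posterior draws (same
trial counts per cell) and compare defective cumulative RT distributions
— RT quantiles within correct and error responses, scaled by the
response proportions so both curves jointly account for all trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignCell
from .hier import ModelVariant, cell_params
from .lba import sample_lba
from .sampler import HierarchicalPosterior

__all__ = [
    "DevianceSummary",
    "deviance_summaries",
    "compare_models",
    "posterior_predictive_cdf",
    "DEFAULT_QUANTILES",
]

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class DevianceSummary:
    """Deviance decomposition of one fitted variant."""

    variant: str
    mean_deviance: float        # D-bar
    deviance_at_mean: float     # D(theta-bar)
    pd_effective: float         # pD
    bpic: float                 # D-bar + 2 pD
    n_samples: int
    dataset_hash: str = ""

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.pd_effective


def _deviance_at(trials: pd.DataFrame, posterior: HierarchicalPosterior,
                 theta_by_pid: dict) -> float:
    from .hier import dataset_loglik

    return -2.0 * dataset_loglik(trials, theta_by_pid, posterior.model)


def deviance_summaries(posterior: HierarchicalPosterior,
                       trials: pd.DataFrame,
                       dataset_hash: str = "",
                       pd_variant: str = "mean") -> DevianceSummary:
    """Deviance decomposition from stored per-sample log-likelihoods.

    pd_variant: "mean" (pD = D-bar - D at the posterior-mean parameters,
    the default) or "min" (pD = D-bar - min over samples of D).
    """
    if posterior.n_retained == 0:
        raise ValueError("empty posterior")
    total_ll = posterior.loglik.sum(axis=2).reshape(-1)   # (S*D,)
    dbar = float((-2.0 * total_ll).mean())
    if pd_variant == "mean":
        means = posterior.participant_mean()
        theta_by_pid = {pid: means[i]
                        for i, pid in enumerate(posterior.participants)}
        dhat = _deviance_at(trials[trials["task"] == "choice"]
                            if "task" in trials.columns else trials,
                            posterior, theta_by_pid)
    elif pd_variant == "min":
        dhat = float((-2.0 * total_ll).min())
    else:
        raise ValueError(f"unknown pd_variant {pd_variant!r}")
    pd_eff = dbar - dhat
    return DevianceSummary(
        variant=posterior.model.name, mean_deviance=dbar,
        deviance_at_mean=dhat, pd_effective=pd_eff, bpic=dbar + 2.0 * pd_eff,
        n_samples=int(total_ll.size), dataset_hash=dataset_hash,
    )


def compare_models(summaries) -> pd.DataFrame:
    """Rank fitted variants by BPIC (ascending).

    All summaries must carry the same dataset hash (fits on different
    preprocessed data are not comparable).  Ties are reported explicitly
    via the `tied_with_best` column.  Negative pD is kept and flagged.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries")
    hashes = {s.dataset_hash for s in summaries}
    if len(hashes) > 1:
        raise ValueError(f"summaries computed on different datasets: {hashes}")
    rows = sorted(summaries, key=lambda s: s.bpic)
    best = rows[0].bpic
    out = pd.DataFrame([{
        "variant": s.variant,
        "mean_deviance": s.mean_deviance,
        "deviance_at_mean": s.deviance_at_mean,
        "pd_effective": s.pd_effective,
        "pd_negative": s.pd_effective < 0,
        "bpic": s.bpic,
        "delta_bpic": s.bpic - best,
        "tied_with_best": np.isclose(s.bpic, best),
    } for s in rows])
    return out


def _defective_quantiles(rt: np.ndarray, correct: np.ndarray,
                         quantiles) -> list[dict]:
    """Quantiles of the correct and error RT distributions, with the
    response proportions that scale a defective CDF."""
    n = len(rt)
    out = []
    for label, mask in (("correct", correct), ("error", ~correct)):
        prop = mask.mean() if n else np.nan
        if mask.sum() == 0:
            out.append({"response": label, "proportion": float(prop),
                        "defined": False,
                        **{f"q{q}": np.nan for q in quantiles}})
            continue
        qs = np.quantile(rt[mask], quantiles)
        out.append({"response": label, "proportion": float(prop),
                    "defined": True,
                    **{f"q{q}": float(v) for q, v in zip(quantiles, qs)}})
    return out


def posterior_predictive_cdf(posterior: HierarchicalPosterior,
                             trials: pd.DataFrame,
                             quantiles=DEFAULT_QUANTILES,
                             n_pp: int = 100,
                             seed=None) -> pd.DataFrame:
    """Observed vs posterior-predictive defective RT distributions.

    For each of `n_pp` random posterior draws, a replicate dataset with
    the observed per-participant, per-cell trial counts is simulated;
    per-cell quantiles of correct/error RTs (pooled over participants)
    and response proportions are summarized by their mean and central 95%
    envelope.  Cells with no error responses are flagged `defined=False`
    rather than imputed.
    """
    if posterior.n_retained == 0:
        raise ValueError("empty posterior")
    rng = np.random.default_rng(seed)
    model = posterior.model
    choice = trials[trials["task"] == "choice"] if "task" in trials.columns \
        else trials
    flat = posterior.flat_theta()                    # (S*D, n_part, P)
    draw_idx = rng.integers(0, flat.shape[0], size=n_pp)

    counts = {}
    obs_rows = []
    for (cond, mom), grp in choice.groupby(["condition", "moment"],
                                           observed=True):
        cell = DesignCell(cond, mom)
        for pid, pgrp in grp.groupby("participant_id"):
            counts[(pid, cell)] = len(pgrp)
        rt = grp["rt_s"].to_numpy(dtype=float)
        corr = grp["response"].to_numpy() == "target"
        for rec in _defective_quantiles(rt, corr, quantiles):
            obs_rows.append({"cell": cell.label, "source": "observed",
                             "draw": -1, **rec})

    pp_rows = []
    pid_index = {pid: i for i, pid in enumerate(posterior.participants)}
    for k, di in enumerate(draw_idx):
        by_cell: dict = {}
        for (pid, cell), n in counts.items():
            theta = flat[di, pid_index[pid]]
            p = cell_params(model, theta, cell)
            rt, is_t, _ = sample_lba(p, n, rng)
            by_cell.setdefault(cell, []).append((rt, is_t))
        for cell, chunks in by_cell.items():
            rt = np.concatenate([c[0] for c in chunks])
            corr = np.concatenate([c[1] for c in chunks])
            for rec in _defective_quantiles(rt, corr, quantiles):
                pp_rows.append({"cell": cell.label, "source": "predicted",
                                "draw": k, **rec})

    obs = pd.DataFrame(obs_rows)
    pp = pd.DataFrame(pp_rows)
    qcols = [f"q{q}" for q in quantiles] + ["proportion"]
    pieces = []
    for (cell, resp), grp in pp.groupby(["cell", "response"]):
        rec = {"cell": cell, "response": resp}
        for c in qcols:
            v = grp[c].to_numpy(dtype=float)
            rec[f"{c}_mean"] = np.nanmean(v) if np.isfinite(v).any() else np.nan
            rec[f"{c}_lo95"] = np.nanquantile(v, 0.025) \
                if np.isfinite(v).any() else np.nan
            rec[f"{c}_hi95"] = np.nanquantile(v, 0.975) \
                if np.isfinite(v).any() else np.nan
        pieces.append(rec)
    agg = pd.DataFrame(pieces)
    merged = obs.drop(columns=["source", "draw"]).merge(
        agg, on=["cell", "response"], suffixes=("_obs", ""))
    return merged
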