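"""Heritability, repeatability and sire PTA / PEV / REL summaries.

Two heritability definitions are carried throughout: h2 includes the
contemporary-group variance (when estimated) in the denominator, h2* does
not. Ratios are available both as plug-in ratios of posterior means and as
per-sample posterior averages; the two differ by a Jensen gap and both are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .edits import PreparedDataset
from .gibbs import PosteriorChains, VarianceComponents, summarize_chains
from .pedigree import UNKNOWN, PedigreeTable

logger = logging.getLogger(__name__)

_CG_NAMES = ("sigma2_hys", "sigma2_hpm")


@dataclass
class GeneticSummary:
    """h2, h2* and repeatability with posterior SDs (None when undefined)."""

    h2: float
    h2_sd: float | None
    h2_star: float
    h2_star_sd: float | None
    r2: float | None
    r2_sd: float | None


@dataclass
class PTAEstimate:
    """Sire predicted transmitting ability with its error variance and reliability."""

    sire_id: object
    n_daughters: int
    pta: float
    pev: float
    rel: float


def _component_sum(vc: VarianceComponents, include_cg: bool) -> float:
    return vc.total(include_cg=include_cg)


def heritability(vc: VarianceComponents, include_cg: bool = True) -> float:
    """sigma2_a over the phenotypic sum; ``include_cg=False`` gives h2*."""
    if "sigma2_a" not in vc:
        raise ValueError("additive variance missing")
    denom = _component_sum(vc, include_cg)
    if denom == 0:
        raise ZeroDivisionError("zero phenotypic variance")
    return vc["sigma2_a"] / denom


def repeatability(vc: VarianceComponents) -> float:
    """(sigma2_a + sigma2_pe) over the full phenotypic sum (cg included if present)."""
    if "sigma2_pe" not in vc:
        raise ValueError(
            "repeatability requires a permanent environmental variance "
            "(single-record models have none)"
        )
    denom = _component_sum(vc, include_cg=True)
    if denom == 0:
        raise ZeroDivisionError("zero phenotypic variance")
    return (vc["sigma2_a"] + vc["sigma2_pe"]) / denom


def _ratio_samples(chains: PosteriorChains, ratio: str) -> np.ndarray:
    names = chains.var_names
    tot = np.zeros(chains.n_stored)
    for v in names:
        tot += chains.variance_chain(v)
    if ratio == "h2":
        num = chains.variance_chain("sigma2_a")
    elif ratio == "h2_star":
        num = chains.variance_chain("sigma2_a")
        for v in names:
            if v in _CG_NAMES:
                tot = tot - chains.variance_chain(v)
    elif ratio == "r2":
        if "sigma2_pe" not in names:
            raise ValueError("repeatability requires sigma2_pe in the chains")
        num = chains.variance_chain("sigma2_a") + chains.variance_chain("sigma2_pe")
    else:
        raise ValueError(f"unknown ratio {ratio!r}")
    return num / tot


def posterior_ratio_chain(chains: PosteriorChains, ratio: str) -> dict:
    """Per-sample posterior mean/SD of a ratio plus the plug-in estimate.

    ``ratio`` is one of ``"h2"``, ``"h2_star"``, ``"r2"``. The per-sample
    estimator averages the ratio over stored samples; the plug-in estimator
    is the same ratio of posterior-mean components.
    """
    samples = _ratio_samples(chains, ratio)
    vc = summarize_chains(chains)
    if ratio == "h2":
        plug = heritability(vc, include_cg=True)
    elif ratio == "h2_star":
        plug = heritability(vc, include_cg=False)
    else:
        plug = repeatability(vc)
    return {
        "mean": float(samples.mean()),
        "sd": float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        "plug_in": float(plug),
    }


def genetic_summary(chains: PosteriorChains) -> GeneticSummary:
    """Plug-in h2, h2* and r2 with per-sample posterior SDs."""
    vc = summarize_chains(chains)
    h2 = posterior_ratio_chain(chains, "h2")
    h2s = posterior_ratio_chain(chains, "h2_star")
    if "sigma2_pe" in vc:
        r2 = posterior_ratio_chain(chains, "r2")
        r2_plug, r2_sd = r2["plug_in"], r2["sd"]
    else:
        r2_plug = r2_sd = None
    return GeneticSummary(
        h2=h2["plug_in"],
        h2_sd=h2["sd"],
        h2_star=h2s["plug_in"],
        h2_star_sd=h2s["sd"],
        r2=r2_plug,
        r2_sd=r2_sd,
    )


def daughter_counts(ped: PedigreeTable, data: PreparedDataset) -> dict:
    """Phenotyped daughters per sire, keyed by pedigree index."""
    counts: dict = {}
    for cow_id in data.cow_ids:
        ix = ped.id_to_index[cow_id]
        s = ped.sire[ix]
        if s != UNKNOWN:
            counts[int(s)] = counts.get(int(s), 0) + 1
    return counts


def sire_pta(
    chains: PosteriorChains,
    ped: PedigreeTable,
    data: PreparedDataset,
    min_daughters: int = 10,
) -> list[PTAEstimate]:
    """PTA, PEV and REL per sire with at least ``min_daughters`` recorded daughters.

    PTA is half the sire's additive effect averaged over stored samples; PEV
    is the variance of the PTA samples; REL = 1 - PEV / posterior-mean
    sigma2_a, clipped into [0, 1] (clipping is logged).
    """
    if chains.additive_samples is None or chains.additive_samples.shape[0] == 0:
        raise ValueError("chains carry no additive-effect samples")
    sa2 = chains.posterior_mean("sigma2_a")
    counts = daughter_counts(ped, data)
    out: list[PTAEstimate] = []
    n_animals = chains.additive_samples.shape[1]
    for sire_ix, n_d in sorted(counts.items()):
        if n_d < min_daughters:
            continue
        if sire_ix >= n_animals:
            logger.warning("sire %s absent from chains; skipped", ped.ids[sire_ix])
            continue
        pta_samples = 0.5 * chains.additive_samples[:, sire_ix]
        pta = float(pta_samples.mean())
        pev = float(pta_samples.var(ddof=1)) if len(pta_samples) > 1 else 0.0
        rel = 1.0 - pev / sa2
        if rel < 0.0 or rel > 1.0:
            logger.warning(
                "REL %.3f for sire %s clipped into [0, 1]", rel, ped.ids[sire_ix]
            )
            rel = float(np.clip(rel, 0.0, 1.0))
        out.append(
            PTAEstimate(
                sire_id=ped.ids[sire_ix],
                n_daughters=int(n_d),
                pta=pta,
                pev=pev,
                rel=float(rel),
            )
        )
    return out


def rel_histogram(ptas: list[PTAEstimate], n_bins: int = 20) -> np.ndarray:
    """Counts of sire REL values in equal-width bins over [0, 1]."""
    rels = np.array([p.rel for p in ptas])
    counts, _ = np.histogram(rels, bins=n_bins, range=(0.0, 1.0))
    return counts
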