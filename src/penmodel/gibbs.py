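"""Single-site Gibbs sampler for location effects and variance components.

Each iteration sweeps every effect level, sampling from its scalar full
conditional with on-the-fly residual adjustment (no mixed-model-equation
solve), then draws each variance from its scaled-inverse-chi-square full
conditional; the additive quadratic form uses a' A^-1 a through the sparse
pedigree inverse. Default priors are flat on the variances (nu = -2, S2 = 0).
The numeric core is compiled with numba.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .modelspec import AssembledSystem

logger = logging.getLogger(__name__)

_KIND = {"fixed": 0, "iid": 1, "additive": 2}
FLAT_PRIOR = (-2.0, 0.0)


@dataclass
class GibbsConfig:
    """Chain-length protocol and variance priors.

    Defaults mirror the estimation protocol: 50,000 iterations, 10,000
    burn-in, store 1 in 10. ``priors`` maps a variance name to scaled-
    inverse-chi-square (nu, S2); unnamed variances get the flat default.
    """

    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    priors: dict = field(default_factory=dict)
    #: extra scalar Gibbs step per cow on the contrast a - pe with a + pe held
    #: fixed; exact, and essential for mixing when cows have many records
    interweave: bool = True

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    def prior_for(self, var_name: str) -> tuple[float, float]:
        return tuple(self.priors.get(var_name, FLAT_PRIOR))


@dataclass
class PosteriorChains:
    """Stored Gibbs samples of variances and (at minimum) additive effects."""

    var_names: tuple[str, ...]
    var_samples: np.ndarray  # (n_stored, n_variances)
    additive_samples: np.ndarray  # (n_stored, n_pedigree_animals)
    animal_ids: np.ndarray
    config: GibbsConfig
    location_samples: np.ndarray | None = None  # (n_stored, total_levels) if stored
    effect_layout: list = field(default_factory=list)  # (name, offset, n_levels)
    warnings: list = field(default_factory=list)

    @property
    def n_stored(self) -> int:
        return self.var_samples.shape[0]

    def variance_chain(self, name: str) -> np.ndarray:
        return self.var_samples[:, self.var_names.index(name)]

    def posterior_mean(self, name: str) -> float:
        return float(self.variance_chain(name).mean())

    def posterior_sd(self, name: str) -> float:
        return float(self.variance_chain(name).std(ddof=1))


@dataclass
class VarianceComponents:
    """Posterior mean and SD per variance component; absent ones are missing keys."""

    means: dict
    sds: dict

    @property
    def cg_names(self) -> list[str]:
        return [k for k in self.means if k in ("sigma2_hys", "sigma2_hpm")]

    def total(self, include_cg: bool = True) -> float:
        tot = 0.0
        for k, v in self.means.items():
            if not include_cg and k in ("sigma2_hys", "sigma2_hpm"):
                continue
            tot += v
        return tot

    def __getitem__(self, key: str) -> float:
        return self.means[key]

    def __contains__(self, key: str) -> bool:
        return key in self.means


@njit(cache=True)
def _gibbs_core(
    y,
    kind,
    varidx,
    nlev,
    constrained,
    lev_off,
    ridx_all,
    rptr_all,
    rptr_off,
    ainv_indptr,
    ainv_indices,
    ainv_data,
    add_k,
    pe_k,
    pair_map,
    nu,
    s2,
    n_iter,
    burn_in,
    thin,
    seed,
    var_out,
    add_out,
    loc_out,
    status,
):  # pragma: no cover - exercised through run_gibbs
    np.random.seed(seed)
    n = y.shape[0]
    K = kind.shape[0]
    V = nu.shape[0]
    total_lev = lev_off[K]
    values = np.zeros(total_lev)
    e = y.copy()

    m = 0.0
    for t in range(n):
        m += y[t]
    m /= n
    vy = 0.0
    for t in range(n):
        vy += (y[t] - m) ** 2
    vy = vy / max(n - 1, 1)
    if vy <= 0.0:
        vy = 1.0
    var = np.empty(V)
    for v in range(V):
        var[v] = vy / V

    for it in range(1, n_iter + 1):
        se2 = var[V - 1]
        for k in range(K):
            off = lev_off[k]
            po = rptr_off[k]
            kk = kind[k]
            vi = varidx[k]
            prior_prec = 0.0
            sa2 = 1.0
            if kk == 1:
                prior_prec = 1.0 / var[vi]
            elif kk == 2:
                sa2 = var[vi]
            for lvl in range(nlev[k]):
                if lvl == constrained[k]:
                    continue
                start = rptr_all[po + lvl]
                end = rptr_all[po + lvl + 1]
                nrec = end - start
                old = values[off + lvl]
                srhs = nrec * old
                for t in range(start, end):
                    srhs += e[ridx_all[t]]
                num = srhs / se2
                if kk == 0:
                    if nrec == 0:
                        continue
                    prec = nrec / se2
                elif kk == 1:
                    prec = nrec / se2 + prior_prec
                else:
                    aii = 0.0
                    od = 0.0
                    for p in range(ainv_indptr[lvl], ainv_indptr[lvl + 1]):
                        j = ainv_indices[p]
                        if j == lvl:
                            aii += ainv_data[p]
                        else:
                            od += ainv_data[p] * values[off + j]
                    prec = nrec / se2 + aii / sa2
                    num -= od / sa2
                if not (prec > 0.0 and np.isfinite(prec)):
                    status[0] = 1
                    status[1] = k
                    return
                newv = num / prec + np.random.normal() / np.sqrt(prec)
                values[off + lvl] = newv
                diff = newv - old
                for t in range(start, end):
                    e[ridx_all[t]] -= diff

        # interweaving: per cow, resample the contrast a - pe given a + pe.
        # The likelihood depends on the pair only through the sum, so the
        # residual vector is untouched; this is a scalar Gibbs update in a
        # rotated coordinate and leaves the stationary distribution invariant.
        if pair_map.shape[0] > 0:
            aoff = lev_off[add_k]
            poff = lev_off[pe_k]
            sa2 = var[varidx[add_k]]
            spe2 = var[varidx[pe_k]]
            for c in range(pair_map.shape[0]):
                i = pair_map[c]
                aii = 0.0
                od = 0.0
                for p in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    j = ainv_indices[p]
                    if j == i:
                        aii += ainv_data[p]
                    else:
                        od += ainv_data[p] * values[aoff + j]
                s = values[aoff + i] + values[poff + c]
                tau = 0.25 * (aii / sa2 + 1.0 / spe2)
                mean = (s * (1.0 / spe2 - aii / sa2) - 2.0 * od / sa2) / (
                    aii / sa2 + 1.0 / spe2
                )
                delta = mean + np.random.normal() / np.sqrt(tau)
                values[aoff + i] = 0.5 * (s + delta)
                values[poff + c] = 0.5 * (s - delta)

        # variances: scaled-inverse-chi-square full conditionals
        for k in range(K):
            kk = kind[k]
            if kk == 0:
                continue
            vi = varidx[k]
            off = lev_off[k]
            ss = 0.0
            if kk == 1:
                for lvl in range(nlev[k]):
                    ss += values[off + lvl] * values[off + lvl]
            else:
                for lvl in range(nlev[k]):
                    vl = values[off + lvl]
                    for p in range(ainv_indptr[lvl], ainv_indptr[lvl + 1]):
                        ss += vl * ainv_data[p] * values[off + ainv_indices[p]]
            df = nlev[k] + nu[vi]
            var[vi] = (ss + nu[vi] * s2[vi]) / np.random.chisquare(df)
        sse = 0.0
        for t in range(n):
            sse += e[t] * e[t]
        dfe = n + nu[V - 1]
        var[V - 1] = (sse + nu[V - 1] * s2[V - 1]) / np.random.chisquare(dfe)

        if it > burn_in and (it - burn_in) % thin == 0:
            sidx = (it - burn_in) // thin - 1
            for v in range(V):
                var_out[sidx, v] = var[v]
            if add_k >= 0 and add_out.shape[1] > 0:
                aoff = lev_off[add_k]
                for lvl in range(nlev[add_k]):
                    add_out[sidx, lvl] = values[aoff + lvl]
            if loc_out.shape[0] > 0:
                for t in range(total_lev):
                    loc_out[sidx, t] = values[t]


def _level_index(codes: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Records grouped by level: sorted record indices + per-level pointers."""
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=n_levels)
    rptr = np.zeros(n_levels + 1, dtype=np.int64)
    np.cumsum(counts, out=rptr[1:])
    return order, rptr


def run_gibbs(
    system: AssembledSystem,
    config: GibbsConfig,
    store_all_locations: bool = False,
) -> PosteriorChains:
    """Run the sampler on an assembled system; deterministic given the seed.

    Sampling order per iteration: fixed factors, random environmental
    factors, additive effects in pedigree order, pe, then all variances.
    Additive-effect samples for every pedigree animal are always stored.
    """
    n = system.n_records
    K = len(system.effects)
    var_names = system.variance_names
    V = len(var_names)

    kind = np.array([_KIND[e.kind] for e in system.effects], dtype=np.int64)
    varidx = np.array(
        [var_names.index(e.var_name) if e.var_name else -1 for e in system.effects],
        dtype=np.int64,
    )
    nlev = np.array([e.n_levels for e in system.effects], dtype=np.int64)
    constrained = np.array([e.constrained for e in system.effects], dtype=np.int64)
    lev_off = np.zeros(K + 1, dtype=np.int64)
    np.cumsum(nlev, out=lev_off[1:])

    ridx_parts, rptr_parts, rptr_off = [], [], np.zeros(K, dtype=np.int64)
    base = 0
    ptr_base = 0
    for k, eff in enumerate(system.effects):
        order, rptr = _level_index(np.asarray(eff.codes, dtype=np.int64), eff.n_levels)
        ridx_parts.append(order)
        rptr_parts.append(rptr + base)
        rptr_off[k] = ptr_base
        base += len(order)
        ptr_base += len(rptr)
    ridx_all = np.concatenate(ridx_parts)
    rptr_all = np.concatenate(rptr_parts)

    add_ks = np.where(kind == 2)[0]
    add_k = int(add_ks[0]) if add_ks.size else -1
    if add_k >= 0:
        ainv = system.ainv.tocsr()
        ainv_indptr = ainv.indptr.astype(np.int64)
        ainv_indices = ainv.indices.astype(np.int64)
        ainv_data = ainv.data.astype(float)
    else:
        ainv_indptr = np.zeros(1, dtype=np.int64)
        ainv_indices = np.zeros(0, dtype=np.int64)
        ainv_data = np.zeros(0, dtype=float)
    nu = np.array([config.prior_for(v)[0] for v in var_names], dtype=float)
    s2 = np.array([config.prior_for(v)[1] for v in var_names], dtype=float)
    for v, name in enumerate(var_names):
        q = n if name == "sigma2_e" else int(nlev[np.where(varidx == v)[0][0]])
        if q + nu[v] <= 0:
            raise ValueError(
                f"improper posterior for {name}: {q} levels with prior nu={nu[v]}"
            )

    pe_ks = [
        k for k, e in enumerate(system.effects) if e.var_name == "sigma2_pe"
    ]
    pe_k = pe_ks[0] if pe_ks else -1
    if (
        config.interweave
        and add_k >= 0
        and pe_k >= 0
        and len(system.cow_to_animal) == system.effects[pe_k].n_levels
    ):
        pair_map = np.asarray(system.cow_to_animal, dtype=np.int64)
    else:
        pair_map = np.zeros(0, dtype=np.int64)

    n_stored = config.n_stored
    var_out = np.empty((n_stored, V))
    add_out = np.empty((n_stored, int(nlev[add_k]) if add_k >= 0 else 0))
    loc_out = (
        np.empty((n_stored, int(lev_off[K]))) if store_all_locations else np.empty((0, 0))
    )
    status = np.zeros(2, dtype=np.int64)

    _gibbs_core(
        np.asarray(system.y, dtype=float),
        kind,
        varidx,
        nlev,
        constrained,
        lev_off,
        ridx_all,
        rptr_all,
        rptr_off,
        ainv_indptr,
        ainv_indices,
        ainv_data,
        add_k,
        pe_k,
        pair_map,
        nu,
        s2,
        config.n_iterations,
        config.burn_in,
        config.thin,
        config.seed,
        var_out,
        add_out,
        loc_out,
        status,
    )
    if status[0]:
        raise FloatingPointError(
            f"non-finite conditional variance while sampling effect "
            f"{system.effects[int(status[1])].name!r}"
        )
    if not np.all(var_out > 0):
        raise FloatingPointError("non-positive variance sample stored")

    chains = PosteriorChains(
        var_names=var_names,
        var_samples=var_out,
        additive_samples=add_out,
        animal_ids=system.pedigree.ids,
        config=config,
        location_samples=loc_out if store_all_locations else None,
        effect_layout=[
            (e.name, int(lev_off[k]), e.n_levels) for k, e in enumerate(system.effects)
        ],
    )
    for name in var_names:
        ess = effective_sample_size(chains.variance_chain(name))
        if ess is not None and ess < 50:
            msg = f"effective sample size for {name} is {ess:.0f} (< 50)"
            logger.warning(msg)
            chains.warnings.append(msg)
    return chains


def summarize_chains(chains: PosteriorChains) -> VarianceComponents:
    """Posterior mean and SD per variance component from the stored samples."""
    if chains.n_stored == 0:
        raise ValueError("no stored samples to summarize")
    means = {v: chains.posterior_mean(v) for v in chains.var_names}
    sds = {
        v: chains.posterior_sd(v) if chains.n_stored > 1 else 0.0
        for v in chains.var_names
    }
    return VarianceComponents(means=means, sds=sds)


def effective_sample_size(x: np.ndarray) -> float | None:
    """ESS of a single chain; None when undefined (constant chain)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4 or np.std(x) == 0:
        return None
    import arviz as az

    with np.errstate(all="ignore"):
        ess = float(az.ess(x))
    return ess if np.isfinite(ess) else None


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float | None:
    """Geweke convergence z-score comparing early and late chain segments.

    Segment means are compared with ESS-adjusted standard errors; None when
    either segment is degenerate.
    """
    x = np.asarray(x, dtype=float)
    a = x[: max(int(first * len(x)), 2)]
    b = x[len(x) - max(int(last * len(x)), 2):]
    se = []
    for seg in (a, b):
        ess = effective_sample_size(seg)
        if ess is None or ess <= 0:
            return None
        se.append(np.std(seg, ddof=1) / np.sqrt(ess))
    denom = float(np.hypot(*se))
    if denom == 0:
        return None
    return float((a.mean() - b.mean()) / denom)


def diagnostics(chains: PosteriorChains) -> dict:
    """Per-variance ESS and Geweke z; |z| > 3 is flagged."""
    report: dict = {}
    for name in chains.var_names:
        x = chains.variance_chain(name)
        ess = effective_sample_size(x)
        z = geweke_z(x)
        report[name] = {
            "n_stored": int(len(x)),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "ess": ess,
            "geweke_z": z,
            "flagged": bool(z is not None and abs(z) > 3),
        }
    return report
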