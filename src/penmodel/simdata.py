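"""Synthetic multi-herd daily-milk-weight datasets with known truth.

Generates pedigreed cows (founder sires and dams, phenotyped daughters),
daily milking records over multiple years with herd-year-season effects,
AR(1) pen-day environmental effects, and pen assignments that are either
random or driven by each cow's trailing 7-day mean yield. The latter
recreates the feedback between phenotype and contemporary-group membership
that makes pen-based groups hard to fit.

Record model (per milking):

    y = mean_yield + afc_effect[class] + dim_curve[class] + hys + pen_day
        + a_cow + pe_cow + e

with a drawn jointly over the pedigree (founders N(0, sigma2_a), offspring
mid-parent plus Mendelian sampling), pe/e iid normal, hys iid normal per
herd-year-quarter, and pen_day a stationary AR(1) over days within each
physical pen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import edits as edits_mod

logger = logging.getLogger(__name__)

START_DATE = date(2020, 1, 1)
#: representative age (months) used when drawing each AFC class
AFC_CLASS_AGES = np.array([22, 24, 26, 28, 30, 32])

_DEFAULT_AFC_P = (0.15, 0.35, 0.25, 0.15, 0.07, 0.03)
_DEFAULT_DIM_CURVE = (4.0, 6.0, 5.5, 5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0)


@dataclass
class SimConfig:
    """Parameters of the synthetic population; all variances are per milking (kg^2)."""

    n_herds: int = 10
    cows_per_herd: int = 100
    n_sires: int = 40
    daughters_per_sire: float | None = None  # expected; derives n_sires when set
    years: int = 5
    seasons_per_year: int = 4
    pens_per_herd: int = 4
    pen_reassign_interval_days: int = 14
    reassign_on_phenotype: bool = False
    milkings_per_day: int = 3
    lactation_length_days: int = 300
    true_sigma2_a: float = 11.0
    true_sigma2_pe: float = 15.0
    true_sigma2_e: float = 14.6
    true_sigma2_hys: float = 10.0
    true_sigma2_pen_day: float = 0.0
    pen_day_autocorr: float = 0.0
    afc_distribution: tuple = _DEFAULT_AFC_P
    dim_curve: tuple = _DEFAULT_DIM_CURVE
    mean_yield: float = 12.0
    afc_effects: tuple = (0.0,) * 6
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "true_sigma2_a",
            "true_sigma2_pe",
            "true_sigma2_e",
            "true_sigma2_hys",
            "true_sigma2_pen_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.pen_day_autocorr < 1.0:
            raise ValueError("pen_day_autocorr must lie in [0, 1)")
        if len(self.afc_distribution) != 6 or not np.isclose(
            sum(self.afc_distribution), 1.0
        ):
            raise ValueError("afc_distribution must be 6 probabilities summing to 1")
        if len(self.dim_curve) != 10:
            raise ValueError("dim_curve must have exactly 10 entries")
        if len(self.afc_effects) != 6:
            raise ValueError("afc_effects must have exactly 6 entries")
        if self.seasons_per_year != 4:
            raise ValueError(
                "seasons_per_year: only 4 (calendar quarters) is supported"
            )
        for name in (
            "n_herds",
            "cows_per_herd",
            "n_sires",
            "years",
            "pens_per_herd",
            "pen_reassign_interval_days",
            "milkings_per_day",
            "lactation_length_days",
        ):
            if getattr(self, name) < (0 if name in ("n_herds", "cows_per_herd") else 1):
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """True parameter values and realized effects behind a simulated dataset."""

    variances: dict
    breeding_values: dict  # animal id -> a
    pe: dict  # cow id -> pe
    hys: dict  # HYS label -> effect
    pen_day: dict  # (herd, pen, iso date) -> effect


@dataclass
class SimOutput:
    records: pd.DataFrame
    cows: pd.DataFrame
    pedigree: pd.DataFrame
    truth: SimTruth


def _empty_output(config: SimConfig) -> SimOutput:
    return SimOutput(
        records=pd.DataFrame(columns=edits_mod.RECORD_COLUMNS),
        cows=pd.DataFrame(columns=edits_mod.COW_COLUMNS),
        pedigree=pd.DataFrame(columns=["animal", "sire", "dam"]),
        truth=SimTruth(
            variances=_true_variances(config),
            breeding_values={},
            pe={},
            hys={},
            pen_day={},
        ),
    )


def _true_variances(config: SimConfig) -> dict:
    return {
        "sigma2_a": config.true_sigma2_a,
        "sigma2_pe": config.true_sigma2_pe,
        "sigma2_e": config.true_sigma2_e,
        "sigma2_hys": config.true_sigma2_hys,
        "sigma2_pen_day": config.true_sigma2_pen_day,
    }


def _ar1_paths(rng, n_series: int, n_days: int, sigma2: float, rho: float) -> np.ndarray:
    """Stationary AR(1) rows: marginal variance sigma2, lag-1 correlation rho."""
    x = np.zeros((n_series, n_days))
    if sigma2 == 0 or n_days == 0:
        return x
    sd = np.sqrt(sigma2)
    x[:, 0] = rng.normal(0.0, sd, n_series)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    for t in range(1, n_days):
        x[:, t] = rho * x[:, t - 1] + rng.normal(0.0, innov_sd, n_series)
    return x


def simulate(config: SimConfig) -> SimOutput:
    """Generate records, cow attributes, pedigree and truth for ``config``."""
    if config.daughters_per_sire:
        n_cows_target = config.n_herds * config.cows_per_herd
        n_sires = max(1, round(n_cows_target / config.daughters_per_sire))
        config = replace(config, n_sires=n_sires, daughters_per_sire=None)
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, C, P = config.n_herds, config.cows_per_herd, config.pens_per_herd
    S = config.milkings_per_day
    L = config.lactation_length_days
    n_cows = H * C
    if n_cows == 0:
        return _empty_output(config)

    herd_of = np.repeat(np.arange(H), C)
    herd_labels = np.array([f"H{h + 1}" for h in range(H)], dtype=object)
    cow_ids = np.array([f"C{i + 1}" for i in range(n_cows)], dtype=object)
    sire_ids = np.array([f"S{i + 1}" for i in range(config.n_sires)], dtype=object)
    dam_ids = np.array([f"D{i + 1}" for i in range(n_cows)], dtype=object)

    # pedigree: unrelated founders, every cow one sire and one (unique) dam;
    # sires are drawn per cow, so daughters spread across herds
    sire_of = rng.integers(0, config.n_sires, n_cows)
    a_sire = rng.normal(0.0, np.sqrt(config.true_sigma2_a), config.n_sires)
    a_dam = rng.normal(0.0, np.sqrt(config.true_sigma2_a), n_cows)
    a_cow = 0.5 * (a_sire[sire_of] + a_dam) + rng.normal(
        0.0, np.sqrt(0.5 * config.true_sigma2_a), n_cows
    )
    pe_cow = rng.normal(0.0, np.sqrt(config.true_sigma2_pe), n_cows)

    calving_day = rng.integers(0, config.years * 365, n_cows)
    afc_cls = rng.choice(6, n_cows, p=np.asarray(config.afc_distribution, dtype=float))
    afc_months = AFC_CLASS_AGES[afc_cls]

    calving_dates = np.array(
        [START_DATE + timedelta(days=int(d)) for d in calving_day], dtype=object
    )
    hys_labels = np.array(
        [
            edits_mod.assign_hys(herd_labels[h], d)
            for h, d in zip(herd_of, calving_dates)
        ],
        dtype=object,
    )
    uniq_hys = pd.unique(hys_labels)
    hys_effect_by_label = dict(
        zip(uniq_hys, rng.normal(0.0, np.sqrt(config.true_sigma2_hys), len(uniq_hys)))
    )
    hys_cow = np.array([hys_effect_by_label[lb] for lb in hys_labels])

    n_days = config.years * 365 + L + 1
    pen_day = _ar1_paths(
        rng, H * P, n_days, config.true_sigma2_pen_day, config.pen_day_autocorr
    ).reshape(H, P, n_days)

    afc_eff = np.asarray(config.afc_effects, dtype=float)
    dim_curve = np.asarray(config.dim_curve, dtype=float)
    static = (
        config.mean_yield + afc_eff[afc_cls] + hys_cow + a_cow + pe_cow
    )  # everything constant within cow

    cur_pen = rng.integers(0, P, n_cows)
    daily_total = np.zeros((n_cows, n_days))
    e_sd = np.sqrt(config.true_sigma2_e)

    chunks: list[tuple] = []
    for t in range(1, n_days):
        dim = t - calving_day
        active = np.flatnonzero((dim >= 1) & (dim <= L))
        if t % config.pen_reassign_interval_days == 0:
            _reassign_pens(
                rng, config, cur_pen, daily_total, herd_of, dim, t, L
            )
        if active.size == 0:
            continue
        dimv = dim[active]
        dim_cls = np.minimum((dimv - 1) // 30, 9)
        base = (
            static[active]
            + dim_curve[dim_cls]
            + pen_day[herd_of[active], cur_pen[active], t]
        )
        day_sum = np.zeros(active.size)
        for s in range(S):
            milk = base + rng.normal(0.0, e_sd, active.size)
            day_sum += milk
            chunks.append((t, active, cur_pen[active].copy(), s + 1, dimv, milk))
        daily_total[active, t] = day_sum / S

    records = _chunks_to_frame(chunks, cow_ids, herd_labels, herd_of)
    cows = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "herd": herd_labels[herd_of],
            "calving_date": [d.isoformat() for d in calving_dates],
            "afc_months": afc_months,
        }
    )
    pedigree = pd.DataFrame(
        {
            "animal": np.concatenate([sire_ids, dam_ids, cow_ids]),
            "sire": ["0"] * (config.n_sires + n_cows) + list(sire_ids[sire_of]),
            "dam": ["0"] * (config.n_sires + n_cows) + list(dam_ids),
        }
    )

    bv = dict(zip(sire_ids, a_sire))
    bv.update(zip(dam_ids, a_dam))
    bv.update(zip(cow_ids, a_cow))
    pen_day_truth = {}
    if config.true_sigma2_pen_day > 0:
        iso = [(START_DATE + timedelta(days=t)).isoformat() for t in range(n_days)]
        for h in range(H):
            for p in range(P):
                for t in range(1, n_days):
                    pen_day_truth[(herd_labels[h], f"P{p + 1}", iso[t])] = float(
                        pen_day[h, p, t]
                    )
    truth = SimTruth(
        variances=_true_variances(config),
        breeding_values=bv,
        pe=dict(zip(cow_ids, pe_cow)),
        hys=hys_effect_by_label,
        pen_day=pen_day_truth,
    )
    return SimOutput(records=records, cows=cows, pedigree=pedigree, truth=truth)


def _reassign_pens(rng, config, cur_pen, daily_total, herd_of, dim, t, L) -> None:
    """Re-rank active cows into pens, per herd, in place.

    Phenotype-driven mode ranks by trailing 7-day mean daily yield (cows
    without history get a random rank); otherwise assignment is a random
    equal split.
    """
    P = config.pens_per_herd
    active = np.flatnonzero((dim >= 1) & (dim <= L))
    if active.size == 0:
        return
    if config.reassign_on_phenotype:
        lo = max(t - 7, 0)
        window = daily_total[active, lo:t]
        n_recorded = (window != 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            trail = window.sum(axis=1) / np.maximum(n_recorded, 1)
        known = n_recorded > 0
        if known.any():
            fill_mu = trail[known].mean()
            fill_sd = trail[known].std() or 1.0
        else:
            fill_mu, fill_sd = 0.0, 1.0
        trail[~known] = rng.normal(fill_mu, fill_sd, (~known).sum())
        score = trail + 1e-9 * rng.standard_normal(active.size)  # tie-break
    else:
        score = rng.standard_normal(active.size)
    for h in np.unique(herd_of[active]):
        mask = herd_of[active] == h
        idx = active[mask]
        order = np.argsort(-score[mask], kind="stable")
        ranks = np.empty(idx.size, dtype=np.int64)
        ranks[order] = np.arange(idx.size)
        cur_pen[idx] = (ranks * P) // idx.size


def _chunks_to_frame(chunks, cow_ids, herd_labels, herd_of) -> pd.DataFrame:
    if not chunks:
        return pd.DataFrame(columns=edits_mod.RECORD_COLUMNS)
    day = np.concatenate([np.full(c[1].size, c[0]) for c in chunks])
    cow_ix = np.concatenate([c[1] for c in chunks])
    pen = np.concatenate([c[2] for c in chunks])
    session = np.concatenate([np.full(c[1].size, c[3]) for c in chunks])
    dim = np.concatenate([c[4] for c in chunks])
    milk = np.concatenate([c[5] for c in chunks])
    iso_by_day = {t: (START_DATE + timedelta(days=int(t))).isoformat() for t in set(day)}
    df = pd.DataFrame(
        {
            "cow_id": cow_ids[cow_ix],
            "herd": herd_labels[herd_of[cow_ix]],
            "pen": np.array([f"P{p + 1}" for p in pen], dtype=object),
            "date": [iso_by_day[t] for t in day],
            "milking": session.astype(int),
            "dim": dim.astype(int),
            "milk_kg": milk,
        }
    )
    return df.sort_values(["cow_id", "dim", "milking"], kind="stable").reset_index(
        drop=True
    )


def write_sim(output: SimOutput, directory) -> dict:
    """Write records.csv, cows.csv, pedigree.csv and truth.csv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": directory / "records.csv",
        "cows": directory / "cows.csv",
        "pedigree": directory / "pedigree.csv",
        "truth": directory / "truth.csv",
    }
    output.records.to_csv(paths["records"], index=False)
    output.cows.to_csv(paths["cows"], index=False)
    output.pedigree.to_csv(paths["pedigree"], index=False)

    t = output.truth
    names: list[str] = []
    vals: list[float] = []
    for k, v in t.variances.items():
        names.append(k)
        vals.append(v)
    for k, v in t.breeding_values.items():
        names.append(f"a:{k}")
        vals.append(v)
    for k, v in t.pe.items():
        names.append(f"pe:{k}")
        vals.append(v)
    for k, v in t.hys.items():
        names.append(f"hys:{k}")
        vals.append(v)
    for (h, p, d), v in t.pen_day.items():
        names.append(f"pen_day:{h}:{p}:{d}")
        vals.append(v)
    pd.DataFrame({"name": names, "value": vals}).to_csv(paths["truth"], index=False)
    return paths


def read_truth(path) -> SimTruth:
    """Round-trip reader for truth.csv."""
    df = pd.read_csv(path, dtype={"name": str})
    variances, bv, pe, hys, pen_day = {}, {}, {}, {}, {}
    for name, value in zip(df["name"], df["value"]):
        if name.startswith("a:"):
            bv[name[2:]] = value
        elif name.startswith("pe:"):
            pe[name[3:]] = value
        elif name.startswith("hys:"):
            hys[name[4:]] = value
        elif name.startswith("pen_day:"):
            _, h, p, d = name.split(":", 3)
            pen_day[(h, p, d)] = value
        else:
            variances[name] = value
    return SimTruth(variances=variances, breeding_values=bv, pe=pe, hys=hys, pen_day=pen_day)
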