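"""Data edits, fixed-effect classes and contemporary-group construction.

Turns raw daily milking records plus cow attributes into the dense factor
codes a model needs: age-at-first-calving class (6 levels), days-in-milk
class (10 x 30 d), herd-year-season of calving (HYS) and herd-pen-milking
date (HPM) contemporary groups, with the minimum-cows-per-group edits
applied as an iterated fixed point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["cow_id", "herd", "pen", "date", "milking", "dim", "milk_kg"]
COW_COLUMNS = ["cow_id", "herd", "calving_date", "afc_months"]


def afc_class(afc_months) -> int:
    """Age-at-first-calving class, 1..6 (<=22, 23-24, 25-26, 27-28, 29-30, 31+).

    Age 30 falls in class 5; class 6 starts at 31 months.
    """
    afc = int(afc_months)
    if afc <= 0:
        raise ValueError(f"age at first calving must be positive, got {afc_months}")
    if afc <= 22:
        return 1
    if afc >= 31:
        return 6
    return 2 + (afc - 23) // 2


def dim_class(dim_days: int) -> int | None:
    """Days-in-milk class 1..10 (30-day bins); ``None`` beyond 300 d (record dropped)."""
    if dim_days < 1:
        raise ValueError(f"days in milk must be >= 1, got {dim_days}")
    if dim_days > 300:
        return None
    return math.ceil(dim_days / 30)


def assign_hys(herd, calving_date) -> str:
    """Herd-year-season label: herd + calving year + calendar quarter."""
    ts = pd.Timestamp(calving_date)
    return f"{herd}-{ts.year}-Q{(ts.month - 1) // 3 + 1}"


def assign_hpm(herd, pen, date) -> str:
    """Herd-pen-milking-date label; all sessions of a day share one level."""
    ts = pd.Timestamp(date)
    return f"{herd}-{pen}-{ts.date().isoformat()}"


def _codes(labels: pd.Series) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(labels)
    return cat.codes.astype(np.int64), list(cat.categories)


@dataclass
class PreparedDataset:
    """Model-ready phenotypes with dense factor codes.

    ``phenotype`` is ``"daily"`` or ``"y305"``. Factor code arrays are
    record-aligned; ``levels[name]`` maps dense code -> label. Daily data
    carry DIM and HPM codes, 305-d data do not.
    """

    phenotype: str
    y: np.ndarray
    afc: np.ndarray
    hys: np.ndarray
    cow: np.ndarray
    dim: np.ndarray | None
    hpm: np.ndarray | None
    levels: dict[str, list]
    cow_ids: list
    n_records_removed: int = 0
    n_cows_removed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    def factor_codes(self, name: str) -> np.ndarray:
        arr = {"AFC": self.afc, "DIM": self.dim, "HYS": self.hys, "HPM": self.hpm}[name]
        if arr is None:
            raise KeyError(f"factor {name} not present for {self.phenotype} phenotype")
        return arr


def _edit_pass(df: pd.DataFrame, min_group: int) -> tuple[pd.DataFrame, int, int]:
    """One sweep: HPM filter (drops records) then HYS filter (drops cows)."""
    n_rec = 0
    hpm_cows = df.groupby("hpm")["cow_id"].transform("nunique")
    bad = hpm_cows < min_group
    n_rec = int(bad.sum())
    df = df[~bad]
    n_cow = 0
    if len(df):
        hys_cows = df.drop_duplicates("cow_id").groupby("hys")["cow_id"].nunique()
        bad_hys = set(hys_cows[hys_cows < min_group].index)
        if bad_hys:
            drop = df["hys"].isin(bad_hys)
            n_cow = int(df.loc[drop, "cow_id"].nunique())
            df = df[~drop]
    return df, n_rec, n_cow


def apply_edits(
    records: pd.DataFrame, cows: pd.DataFrame, min_group: int = 25
) -> PreparedDataset:
    """Prepare daily records: classes, contemporary groups and group-size edits.

    Removes records in HPM groups with fewer than ``min_group`` distinct cows
    and all records of cows in HYS groups with fewer than ``min_group``
    distinct cows, iterating until both minima hold simultaneously (removals
    shrink other groups, so a single pass is not enough). Records beyond
    300 days in milk are dropped before grouping.
    """
    records = records.copy()
    cows = cows.copy()
    _check_cow_attributes(cows)
    unknown = set(records["cow_id"]) - set(cows["cow_id"])
    if unknown:
        raise ValueError(f"records reference cows without attributes: {sorted(unknown)[:10]}")

    n0 = len(records)
    records["dim"] = records["dim"].astype(int)
    over = records["dim"] > 300
    if over.any():
        logger.info("dropping %d records with DIM > 300", int(over.sum()))
    records = records[~over & (records["dim"] >= 1)]

    cows = cows.set_index("cow_id")
    cal = pd.to_datetime(cows["calving_date"])
    hys_of_cow = {
        cid: assign_hys(cows.at[cid, "herd"], cal[cid]) for cid in cows.index
    }
    dates = pd.to_datetime(records["date"]).dt.date.astype(str)
    df = records.assign(
        hys=records["cow_id"].map(hys_of_cow),
        hpm=records["herd"].astype(str) + "-" + records["pen"].astype(str) + "-" + dates,
    )

    rec_removed = cow_removed = 0
    while True:
        df, nr, nc = _edit_pass(df, min_group)
        rec_removed += nr
        cow_removed += nc
        if nr == 0 and nc == 0:
            break
    if df.empty:
        raise ValueError("no records survive the contemporary-group minima")
    logger.info(
        "edits: %d of %d records removed (%d via HYS cows)", n0 - len(df), n0, cow_removed
    )

    df = df.reset_index(drop=True)
    afc_codes = (
        df["cow_id"].map(lambda c: afc_class(cows.at[c, "afc_months"])).to_numpy() - 1
    )
    dim_codes = (np.ceil(df["dim"].to_numpy() / 30.0) - 1).astype(np.int64)
    hys_codes, hys_levels = _codes(df["hys"])
    hpm_codes, hpm_levels = _codes(df["hpm"])
    cow_codes, cow_levels = _codes(df["cow_id"])
    return PreparedDataset(
        phenotype="daily",
        y=df["milk_kg"].to_numpy(float),
        afc=afc_codes.astype(np.int64),
        dim=dim_codes,
        hys=hys_codes,
        hpm=hpm_codes,
        cow=cow_codes,
        levels={
            "AFC": list(range(1, 7)),
            "DIM": list(range(1, 11)),
            "HYS": hys_levels,
            "HPM": hpm_levels,
        },
        cow_ids=cow_levels,
        n_records_removed=n0 - len(df),
        n_cows_removed=cow_removed,
    )


def _check_cow_attributes(cows: pd.DataFrame) -> None:
    afc = cows["afc_months"].astype(int)
    odd = cows.loc[(afc < 18) | (afc > 40), "cow_id"]
    if len(odd):
        logger.warning(
            "%d cows with age at first calving outside 18..40 months (kept)", len(odd)
        )


def make_305d(
    records: pd.DataFrame, cows: pd.DataFrame, min_days: int = 250
) -> pd.DataFrame:
    """305-d yield per cow: daily totals over DIM 1-300 scaled by 305/300.

    Returns one row per cow with ``y305``, ``n_days`` and a ``flagged``
    column marking cows with fewer than ``min_days`` recorded days. Cows
    with no usable records are excluded.
    """
    rec = records[(records["dim"] >= 1) & (records["dim"] <= 300)]
    if rec.empty:
        return pd.DataFrame(columns=["cow_id", "y305", "n_days", "flagged"])
    daily = rec.groupby(["cow_id", "dim"])["milk_kg"].sum()
    per_cow = daily.groupby("cow_id").agg(total="sum", n_days="count")
    out = per_cow.reset_index()
    out["y305"] = out.pop("total") * (305.0 / 300.0)
    out["flagged"] = out["n_days"] < min_days
    return out[["cow_id", "y305", "n_days", "flagged"]]


def prepare_305d(
    records: pd.DataFrame,
    cows: pd.DataFrame,
    min_group: int = 25,
    min_days: int = 250,
    drop_flagged: bool = False,
) -> PreparedDataset:
    """One 305-d record per cow with AFC and HYS codes, HYS minimum enforced.

    ``drop_flagged=True`` excludes cows with fewer than ``min_days`` recorded
    days (incomplete lactations), as an evaluation restricted to completed
    305-d records would. The HYS >= ``min_group``-cows edit is iterated to a
    fixed point on the per-cow table (a single pass suffices there, since
    removing a cow only affects her own group).
    """
    y305 = make_305d(records, cows, min_days=min_days)
    if drop_flagged:
        y305 = y305[~y305["flagged"]].reset_index(drop=True)
    if y305.empty:
        raise ValueError("no cows with usable 305-d records")
    df = y305.merge(
        cows.rename(columns={"herd": "herd_"}), on="cow_id", how="inner"
    )
    df["hys"] = [
        assign_hys(h, c) for h, c in zip(df["herd_"], pd.to_datetime(df["calving_date"]))
    ]
    while True:
        counts = df.groupby("hys")["cow_id"].nunique()
        bad = set(counts[counts < min_group].index)
        if not bad:
            break
        df = df[~df["hys"].isin(bad)]
    if df.empty:
        raise ValueError("no cows survive the HYS minimum for the 305-d dataset")
    df = df.reset_index(drop=True)
    hys_codes, hys_levels = _codes(df["hys"])
    cow_codes, cow_levels = _codes(df["cow_id"])
    afc_codes = df["afc_months"].map(afc_class).to_numpy() - 1
    return PreparedDataset(
        phenotype="y305",
        y=df["y305"].to_numpy(float),
        afc=afc_codes.astype(np.int64),
        dim=None,
        hys=hys_codes,
        hpm=None,
        cow=cow_codes,
        levels={"AFC": list(range(1, 7)), "HYS": hys_levels},
        cow_ids=cow_levels,
        n_cows_removed=int(len(y305) - df["cow_id"].nunique()),
    )


def read_records(path) -> pd.DataFrame:
    """Read a records.csv (cow_id, herd, pen, date, milking, dim, milk_kg)."""
    df = pd.read_csv(path, dtype={"cow_id": str, "herd": str, "pen": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns {sorted(missing)}")
    return df


def read_cows(path) -> pd.DataFrame:
    """Read a cows.csv (cow_id, herd, calving_date, afc_months)."""
    df = pd.read_csv(path, dtype={"cow_id": str, "herd": str})
    missing = set(COW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cow attribute file missing columns {sorted(missing)}")
    return df
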