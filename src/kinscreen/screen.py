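"""Thermal-shift screen assembly: delta-Tm matrix, hit calling, summaries.

Each (kinase, compound) pair is measured in replicate wells.  The thermal
shift dTm is the replicate-mean Tm minus the mean Tm of that kinase's DMSO
vehicle-control wells; negative means are reported as 0 degC (stabilisation,
not destabilisation, is the readout of interest).  A compound is a hit for a
kinase when its reported shift is at or above ``multiplier`` times the
standard deviation of the per-well DMSO shifts for that kinase (default 2x).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percentage
from .errors import MalformedInputError, MissingReferenceError, UndefinedRateError
from .melt import DMSO, BoltzmannFit

logger = logging.getLogger(__name__)

DEFAULT_MULTIPLIER = 2.0
PROMISCUITY_CUTOFF = 10  # compounds hitting >= this many kinases are "promiscuous"


@dataclass(frozen=True)
class ReferenceStats:
    """DMSO vehicle-control statistics defining a kinase's hit threshold."""

    kinase_id: str
    tm_mean: float
    tm_sd: float
    dtm_sd: float
    n_wells: int

    def __post_init__(self):
        if self.n_wells < 2:
            raise MalformedInputError(f"{self.kinase_id}: reference needs >= 2 wells")
        if self.tm_sd < 0 or self.dtm_sd < 0:
            raise MalformedInputError(f"{self.kinase_id}: negative SD")


@dataclass(frozen=True)
class ThermalShift:
    """Replicate-mean thermal shift for one (kinase, compound) pair."""

    kinase_id: str
    compound_id: str
    dtm_mean: float
    dtm_sd: float
    n_replicates: int
    clamped: bool
    dtm_reported: float
    absent: bool = False


@dataclass(frozen=True)
class CompoundRecord:
    """Library annotation for one compound."""

    compound_id: str
    name: str = ""
    human_targets: tuple[str, ...] = ()
    fda_approved: bool = False


def _tms(fits: Iterable[BoltzmannFit | float]) -> np.ndarray:
    return np.array([f.tm if isinstance(f, BoltzmannFit) else float(f) for f in fits])


def build_reference(kinase_id: str, dmso_fits: Sequence[BoltzmannFit | float]) -> ReferenceStats:
    """DMSO reference statistics from QC-passing control wells of one kinase.

    ``dtm_sd`` is the sample SD (n-1 denominator) of the per-well control Tm
    values about their mean — i.e. the spread of per-well DMSO "shifts".
    """
    tms = _tms(dmso_fits)
    if len(tms) < 2:
        raise MissingReferenceError(
            f"kinase {kinase_id}: {len(tms)} passing DMSO control well(s), need >= 2"
        )
    tm_mean = float(np.mean(tms))
    sd = float(np.std(tms, ddof=1))
    return ReferenceStats(kinase_id=kinase_id, tm_mean=tm_mean, tm_sd=sd, dtm_sd=sd, n_wells=len(tms))


def delta_tm(
    compound_id: str,
    compound_fits: Sequence[BoltzmannFit | float],
    ref: ReferenceStats,
    clamp: bool = True,
) -> ThermalShift:
    """Replicate-mean shift vs the DMSO reference; optionally clamp at 0 degC.

    A pair with no passing replicate is returned as an absent record (never a
    hit) rather than an error: dropped wells are an expected screen outcome.
    """
    tms = _tms(compound_fits)
    if len(tms) == 0:
        return ThermalShift(
            kinase_id=ref.kinase_id,
            compound_id=compound_id,
            dtm_mean=math.nan,
            dtm_sd=math.nan,
            n_replicates=0,
            clamped=False,
            dtm_reported=math.nan,
            absent=True,
        )
    dtm_mean = float(np.mean(tms)) - ref.tm_mean
    dtm_sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0
    clamped = bool(clamp and dtm_mean < 0.0)
    reported = max(0.0, dtm_mean) if clamp else dtm_mean
    return ThermalShift(
        kinase_id=ref.kinase_id,
        compound_id=compound_id,
        dtm_mean=dtm_mean,
        dtm_sd=dtm_sd,
        n_replicates=len(tms),
        clamped=clamped,
        dtm_reported=reported,
    )


@dataclass(frozen=True)
class ScreenMatrix:
    """Compound x kinase delta-Tm matrix with thresholds and hit flags.

    All frames are indexed by ``compound_id`` with one column per
    ``kinase_id``; ``NaN`` cells are absent measurements.  ``hits`` and
    ``thresholds`` are populated by :func:`call_hits`.
    """

    dtm_raw: pd.DataFrame
    dtm_reported: pd.DataFrame
    n_replicates: pd.DataFrame
    dmso_sd: pd.Series
    multiplier: float | None = None
    thresholds: pd.Series | None = None
    hits: pd.DataFrame | None = None

    @property
    def kinases(self) -> list[str]:
        return list(self.dtm_reported.columns)

    @property
    def compounds(self) -> list[str]:
        return list(self.dtm_reported.index)

    def __post_init__(self):
        for frame in (self.dtm_raw, self.n_replicates):
            if not (
                frame.index.equals(self.dtm_reported.index)
                and frame.columns.equals(self.dtm_reported.columns)
            ):
                raise MalformedInputError("matrix frames have inconsistent dimensions")
        if not set(self.dtm_reported.columns) <= set(self.dmso_sd.index):
            missing = set(self.dtm_reported.columns) - set(self.dmso_sd.index)
            raise MalformedInputError(f"kinases without DMSO SD: {sorted(missing)}")


def build_matrix(
    shifts: Iterable[ThermalShift],
    references: Mapping[str, ReferenceStats] | Mapping[str, float],
) -> ScreenMatrix:
    """Pivot per-pair shifts into a :class:`ScreenMatrix` (no hits yet)."""
    rows = [
        {
            "compound_id": s.compound_id,
            "kinase_id": s.kinase_id,
            "dtm_mean": s.dtm_mean,
            "dtm_reported": s.dtm_reported,
            "n_replicates": s.n_replicates,
        }
        for s in shifts
    ]
    if not rows:
        raise MalformedInputError("no thermal shifts supplied")
    df = pd.DataFrame(rows)
    dup = df.duplicated(["compound_id", "kinase_id"])
    if dup.any():
        raise MalformedInputError(f"duplicate (kinase, compound) shifts: {df[dup].iloc[0].tolist()}")

    def pivot(col):
        return df.pivot(index="compound_id", columns="kinase_id", values=col).sort_index(
            axis=0
        ).sort_index(axis=1)

    sd = pd.Series(
        {
            k: (v.dtm_sd if isinstance(v, ReferenceStats) else float(v))
            for k, v in references.items()
        }
    ).sort_index()
    return ScreenMatrix(
        dtm_raw=pivot("dtm_mean"),
        dtm_reported=pivot("dtm_reported"),
        n_replicates=pivot("n_replicates").fillna(0).astype(int),
        dmso_sd=sd,
    )


def call_hits(matrix: ScreenMatrix, multiplier: float = DEFAULT_MULTIPLIER) -> ScreenMatrix:
    """Flag hits: reported shift at or above ``multiplier * dmso_sd`` (inclusive).

    A kinase whose DMSO SD is exactly 0 has a degenerate threshold; there any
    strictly positive shift is a hit and a warning is logged.
    """
    if multiplier <= 0:
        raise MalformedInputError("multiplier must be positive")
    sd = matrix.dmso_sd.reindex(matrix.dtm_reported.columns)
    if sd.isna().any():
        raise MissingReferenceError(
            f"no DMSO SD for kinase(s): {sorted(sd.index[sd.isna()])}"
        )
    thresholds = multiplier * sd
    reported = matrix.dtm_reported
    hits = reported.ge(thresholds, axis=1)
    zero_sd = thresholds.index[thresholds == 0.0]
    if len(zero_sd):
        logger.warning(
            "zero DMSO SD for kinase(s) %s: every strictly positive shift counts as a hit",
            list(zero_sd),
        )
        hits[zero_sd] = reported[zero_sd] > 0.0
    hits = hits & reported.notna()  # absent cells are never hits
    return replace(matrix, multiplier=float(multiplier), thresholds=thresholds, hits=hits)


def _require_hits(matrix: ScreenMatrix) -> pd.DataFrame:
    if matrix.hits is None:
        raise MalformedInputError("hits not called yet; run call_hits first")
    return matrix.hits


def kinase_hit_count(matrix: ScreenMatrix) -> pd.Series:
    """Number of compounds flagged as hits for each kinase (Fig-2b-style)."""
    return _require_hits(matrix).sum(axis=0).astype(int)


def hit_rate_percent(n_hits: int, n_compounds: int) -> float:
    """Screen hit rate as a half-up one-decimal percentage."""
    if n_compounds <= 0:
        raise UndefinedRateError("hit rate undefined for zero compounds")
    if not 0 <= n_hits <= n_compounds:
        raise MalformedInputError(f"n_hits {n_hits} outside [0, {n_compounds}]")
    return percentage(n_hits, n_compounds, ndigits=1)


def compound_promiscuity(
    matrix: ScreenMatrix, cutoff: int = PROMISCUITY_CUTOFF
) -> tuple[pd.Series, dict]:
    """Per-compound promiscuity (kinases hit) and tail/zero summary."""
    counts = _require_hits(matrix).sum(axis=1).astype(int)
    summary = {
        "n_compounds": int(len(counts)),
        "n_zero_hit": int((counts == 0).sum()),
        "promiscuity_cutoff": int(cutoff),
        "n_at_least_cutoff": int((counts >= cutoff).sum()),
    }
    return counts, summary


def screen_report(
    matrix: ScreenMatrix,
    compounds: Sequence[CompoundRecord] | None = None,
    promiscuity_cutoff: int = PROMISCUITY_CUTOFF,
) -> dict:
    """JSON-serialisable screen summary (hit counts, promiscuity, FDA subset).

    Unknown compound ids (present in the matrix but missing from the
    annotation table) are kept, flagged unknown, and logged.
    """
    hits = _require_hits(matrix)
    by_kinase = kinase_hit_count(matrix).sort_values(ascending=False)
    by_compound, prom_summary = compound_promiscuity(matrix, promiscuity_cutoff)
    by_compound = by_compound.sort_values(ascending=False)
    n_compounds = len(matrix.compounds)

    annotations = {c.compound_id: c for c in compounds} if compounds is not None else {}
    unknown = sorted(set(matrix.compounds) - set(annotations)) if compounds is not None else []
    if unknown:
        logger.warning("%d compound id(s) missing from the annotation table", len(unknown))

    report = {
        "n_kinases": len(matrix.kinases),
        "n_compounds": n_compounds,
        "multiplier": matrix.multiplier,
        "total_hits": int(hits.values.sum()),
        "kinase_hit_counts": [
            {
                "kinase_id": k,
                "n_hits": int(n),
                "hit_rate_percent": hit_rate_percent(int(n), n_compounds),
            }
            for k, n in by_kinase.items()
        ],
        "compound_promiscuity": [
            {"compound_id": c, "n_kinases_stabilized": int(n)} for c, n in by_compound.items()
        ],
        **prom_summary,
        "unknown_compounds": unknown,
    }
    if compounds is not None:
        fda = [
            {
                "compound_id": c.compound_id,
                "name": c.name,
                "n_kinases_stabilized": int(by_compound.get(c.compound_id, 0)),
            }
            for c in compounds
            if c.fda_approved and c.compound_id in by_compound.index
        ]
        fda.sort(key=lambda r: (-r["n_kinases_stabilized"], r["compound_id"]))
        report["fda_approved"] = {"n_compounds": len(fda), "compounds": fda}
    return report


def matrix_from_fit_table(
    fit_table: pd.DataFrame,
    clamp: bool = True,
    multiplier: float | None = DEFAULT_MULTIPLIER,
) -> ScreenMatrix:
    """Assemble the screen matrix from a per-well fit table.

    The table needs columns ``kinase_id, compound_id, replicate, tm_c`` and
    optionally ``qc`` (only ``pass`` rows are used) — the dialect written by
    :func:`kinscreen.io.write_fit_table`.  Wells with ``compound_id == DMSO``
    form each kinase's reference; every kinase must keep at least two passing
    control wells.
    """
    required = {"kinase_id", "compound_id", "replicate", "tm_c"}
    missing = required - set(fit_table.columns)
    if missing:
        raise MalformedInputError(f"fit table missing column(s): {sorted(missing)}")
    df = fit_table
    if "qc" in df.columns:
        df = df[df["qc"] == "pass"]

    references: dict[str, ReferenceStats] = {}
    kinases = sorted(fit_table["kinase_id"].unique())
    for kinase in kinases:
        ctl = df[(df["kinase_id"] == kinase) & (df["compound_id"] == DMSO)]
        references[kinase] = build_reference(kinase, ctl["tm_c"].tolist())

    shifts: list[ThermalShift] = []
    all_pairs = fit_table[fit_table["compound_id"] != DMSO][
        ["kinase_id", "compound_id"]
    ].drop_duplicates()
    passing = df[df["compound_id"] != DMSO].groupby(["kinase_id", "compound_id"])["tm_c"]
    groups = {key: vals.tolist() for key, vals in passing}
    for kinase, compound in all_pairs.itertuples(index=False):
        tms = groups.get((kinase, compound), [])
        shifts.append(delta_tm(compound, tms, references[kinase], clamp=clamp))
    matrix = build_matrix(shifts, references)
    return call_hits(matrix, multiplier) if multiplier is not None else matrix


def matrix_from_dtm(
    dtm: pd.DataFrame,
    dmso_sd: Mapping[str, float] | pd.Series,
    multiplier: float | None = DEFAULT_MULTIPLIER,
    clamp: bool = True,
) -> ScreenMatrix:
    """Re-analyse an externally computed compound x kinase delta-Tm table.

    ``dtm`` is indexed by compound with one column per kinase (the shape of a
    published supplementary matrix); per-kinase DMSO SDs must be supplied
    separately since such tables usually omit them.
    """
    reported = dtm.clip(lower=0.0) if clamp else dtm.copy()
    n_rep = dtm.notna().astype(int)
    matrix = ScreenMatrix(
        dtm_raw=dtm.copy(),
        dtm_reported=reported,
        n_replicates=n_rep,
        dmso_sd=pd.Series(dict(dmso_sd)) if not isinstance(dmso_sd, pd.Series) else dmso_sd,
    )
    return call_hits(matrix, multiplier) if multiplier is not None else matrix

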