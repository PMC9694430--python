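"""Readers and writers for every file dialect the pipeline touches.

Conventions: CSV for raw plate reads, TSV for matrices and tables (compound
names may contain commas), UTF-8, '.' decimal separator, no thousands
separators.  Lines starting with '#' are stamp/comment lines and are skipped
by every reader, so stamped artifacts round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .melt import BoltzmannFit, MeltCurve, QCVerdict
from .screen import CompoundRecord, ScreenMatrix
from .selection import KinaseGene

PLATE_COLUMNS = [
    "plate_id",
    "well_id",
    "kinase_id",
    "compound_id",
    "replicate",
    "temperature_c",
    "fluorescence",
]

FIT_COLUMNS = [
    "plate_id",
    "well_id",
    "kinase_id",
    "compound_id",
    "replicate",
    "tm_c",
    "slope_c",
    "f_pre",
    "f_post",
    "r_squared",
    "rmse",
    "converged",
    "qc",
    "qc_reasons",
]


def _write_text(path: Path, text: str, stamp: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prefix = f"# {stamp}\n" if stamp else ""
    path.write_text(prefix + text, encoding="utf-8")


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    blank = df[column].str.strip() == ""
    converted = pd.to_numeric(df[column].where(~blank), errors="coerce")
    bad = converted.isna() & ~blank
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {df[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    return converted


# --- raw plate CSV ----------------------------------------------------------


def write_plate_csv(curves: Iterable[MeltCurve], path: Path, stamp: str | None = None) -> None:
    rows = []
    for c in curves:
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append((c.plate_id, c.well_id, c.kinase_id, c.compound_id, c.replicate, t, f))
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    _write_text(Path(path), df.to_csv(index=False), stamp)


def read_plate_csv(path: Path) -> list[MeltCurve]:
    """Parse a long-format plate CSV into per-well melt curves.

    Rows are grouped by (plate, well) and sorted by temperature; a duplicate
    temperature within one well, a missing column, or a non-numeric reading
    raises :class:`ParseError` identifying the problem.
    """
    path = Path(path)
    df = _read_table(path, sep=",")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("replicate", "temperature_c", "fluorescence"):
        df[col] = _numeric(df, col, path)
    dup = df.duplicated(["plate_id", "well_id", "temperature_c"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate reading for well {row['plate_id']}/{row['well_id']} "
            f"at {row['temperature_c']} degC"
        )
    curves = []
    for (plate, well), grp in df.groupby(["plate_id", "well_id"], sort=True):
        grp = grp.sort_values("temperature_c")
        meta = grp.iloc[0]
        curves.append(
            MeltCurve(
                plate_id=plate,
                well_id=well,
                kinase_id=meta["kinase_id"],
                compound_id=meta["compound_id"],
                replicate=int(meta["replicate"]),
                temperatures=grp["temperature_c"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
            )
        )
    return curves


# --- per-well fit table -----------------------------------------------------


def fits_to_table(
    results: Sequence[tuple[MeltCurve, BoltzmannFit | None, QCVerdict]]
) -> pd.DataFrame:
    rows = []
    for curve, fit, qc in results:
        rows.append(
            {
                "plate_id": curve.plate_id,
                "well_id": curve.well_id,
                "kinase_id": curve.kinase_id,
                "compound_id": curve.compound_id,
                "replicate": curve.replicate,
                "tm_c": fit.tm if fit else np.nan,
                "slope_c": fit.slope if fit else np.nan,
                "f_pre": fit.f_pre if fit else np.nan,
                "f_post": fit.f_post if fit else np.nan,
                "r_squared": fit.r_squared if fit else np.nan,
                "rmse": fit.rmse if fit else np.nan,
                "converged": bool(fit.converged) if fit else False,
                "qc": "pass" if qc.passed else "fail",
                "qc_reasons": ";".join(qc.reasons),
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def write_fit_table(table: pd.DataFrame, path: Path, stamp: str | None = None) -> None:
    _write_text(Path(path), table.to_csv(sep="\t", index=False, float_format="%.6f"), stamp)


def read_fit_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path, sep="\t")
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("replicate", "tm_c", "slope_c", "f_pre", "f_post", "r_squared", "rmse"):
        df[col] = _numeric(df, col, path)
    df["converged"] = df["converged"].isin(["True", "true", "1"])
    return df


# --- delta-Tm matrix and companions -----------------------------------------


def write_dtm_matrix(matrix: ScreenMatrix, path: Path, stamp: str | None = None) -> None:
    """Reported delta-Tm TSV: compound_id first, one column per kinase."""
    df = matrix.dtm_reported.reset_index().rename(columns={"index": "compound_id"})
    _write_text(Path(path), df.to_csv(sep="\t", index=False, float_format="%.6f"), stamp)


def read_dtm_matrix(path: Path) -> pd.DataFrame:
    """Read a compound x kinase delta-Tm TSV (blank cells become absent)."""
    path = Path(path)
    df = _read_table(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a compound column plus kinase columns")
    first = df.columns[0]
    if df[first].duplicated().any():
        dup_id = df[first][df[first].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate compound id {dup_id!r}")
    for col in df.columns[1:]:
        df[col] = _numeric(df, col, path)
    out = df.set_index(first)
    out.index.name = "compound_id"
    out.columns.name = "kinase_id"
    return out


def write_hits(matrix: ScreenMatrix, path: Path, stamp: str | None = None) -> None:
    if matrix.hits is None:
        raise ParseError("hits not called; nothing to write")
    df = matrix.hits.astype(int).reset_index()
    _write_text(Path(path), df.to_csv(sep="\t", index=False), stamp)


def read_hits(path: Path) -> pd.DataFrame:
    df = read_dtm_matrix(path)
    return df.fillna(0).astype(int).astype(bool)


def write_thresholds(matrix: ScreenMatrix, path: Path, stamp: str | None = None) -> None:
    if matrix.thresholds is None:
        raise ParseError("hits not called; thresholds unavailable")
    df = pd.DataFrame(
        {
            "kinase_id": matrix.thresholds.index,
            "dmso_sd": matrix.dmso_sd.reindex(matrix.thresholds.index).to_numpy(),
            "threshold": matrix.thresholds.to_numpy(),
        }
    )
    _write_text(Path(path), df.to_csv(sep="\t", index=False, float_format="%.6f"), stamp)


def read_thresholds(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path, sep="\t")
    for col in ("kinase_id", "dmso_sd", "threshold"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["dmso_sd"] = _numeric(df, "dmso_sd", path)
    df["threshold"] = _numeric(df, "threshold", path)
    return df


def write_report(report: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# --- compound annotations ---------------------------------------------------


def read_compounds_csv(path: Path) -> list[CompoundRecord]:
    """Compound annotation CSV: compound_id,name,human_targets,fda_approved.

    ``human_targets`` is ';'-separated; ``fda_approved`` is true/false.
    """
    path = Path(path)
    df = _read_table(path, sep=",")
    for col in ("compound_id", "name", "human_targets", "fda_approved"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["compound_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate compound ids")
    return [
        CompoundRecord(
            compound_id=row.compound_id,
            name=row.name,
            human_targets=tuple(t for t in row.human_targets.split(";") if t),
            fda_approved=row.fda_approved.strip().lower() in {"true", "1", "yes"},
        )
        for row in df.itertuples(index=False)
    ]


# --- kinome tables ----------------------------------------------------------


def read_id_list(path: Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def write_id_list(ids: Iterable[str], path: Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids), encoding="utf-8")


def load_genes(
    expression_path: Path, families_path: Path, flags_path: Path | None = None
) -> list[KinaseGene]:
    """Assemble gene records from expression, family and domain-flag TSVs."""
    expression_path, families_path = Path(expression_path), Path(families_path)
    expr = _read_table(expression_path, sep="\t")
    if "locus_id" not in expr.columns or expr.shape[1] < 2:
        raise ParseError(f"{expression_path}: need locus_id plus >= 1 library column")
    lib_cols = [c for c in expr.columns if c != "locus_id"]
    for col in lib_cols:
        expr[col] = _numeric(expr, col, expression_path)
    fam = _read_table(families_path, sep="\t")
    for col in ("locus_id", "family", "group"):
        if col not in fam.columns:
            raise ParseError(f"{families_path}: missing column {col!r}")
    fam = fam.set_index("locus_id")
    flags = None
    if flags_path is not None:
        fl = _read_table(Path(flags_path), sep="\t")
        for col in ("locus_id", "has_full_domain"):
            if col not in fl.columns:
                raise ParseError(f"{flags_path}: missing column {col!r}")
        flags = fl.set_index("locus_id")["has_full_domain"].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes"}
        )
    genes = []
    for row in expr.itertuples(index=False):
        locus = row.locus_id
        if locus not in fam.index:
            raise ParseError(f"{families_path}: no family entry for {locus}")
        genes.append(
            KinaseGene(
                locus_id=locus,
                family=fam.at[locus, "family"],
                group=fam.at[locus, "group"],
                expression=np.array([getattr(row, c) for c in lib_cols], dtype=float),
                has_full_domain=bool(flags[locus]) if flags is not None else True,
            )
        )
    return genes


def read_network_tsv(path: Path):
    from .selection import GeneNetwork

    path = Path(path)
    df = _read_table(path, sep="\t")
    for col in ("gene_a", "gene_b", "weight"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["weight"] = _numeric(df, "weight", path)
    return GeneNetwork.from_edges(
        [(r.gene_a, r.gene_b, r.weight) for r in df.itertuples(index=False)]
    )


def write_kinome(sim, out_dir: Path, stamp: str | None = None) -> dict[str, Path]:
    """Write a :class:`~kinscreen.simulate.KinomeSim` as its input-file set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "families": out_dir / "families.tsv",
        "network": out_dir / "network.tsv",
        "flags": out_dir / "domain_flags.tsv",
        "seeds": out_dir / "trait_seeds.txt",
        "curated": out_dir / "curated.txt",
        "failed": out_dir / "synthesis_failed.txt",
    }
    _write_text(paths["expression"], sim.expression.to_csv(sep="\t", index=False), stamp)
    _write_text(paths["families"], sim.families.to_csv(sep="\t", index=False), stamp)
    _write_text(paths["network"], sim.network.to_csv(sep="\t", index=False), stamp)
    _write_text(paths["flags"], sim.flags.to_csv(sep="\t", index=False), stamp)
    write_id_list(sim.seed_ids, paths["seeds"])
    write_id_list(sim.curated_ids, paths["curated"])
    write_id_list(sim.failed_ids, paths["failed"])
    return paths
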