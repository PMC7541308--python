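"""Readers and writers for on-disk artifacts.

Formats: TSV abundance matrix (protein ids in the first column, sample ids as
header), CSV sample sheet, GMT gene sets, TSV result tables, JSON QC report
and config echo.  Missing abundance cells are written as empty strings and
read back into the boolean mask; values round-trip at full precision via
``repr``-style formatting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AbundanceMatrix, GeneSetCollection, SampleMeta

logger = logging.getLogger("protnet")

REPORT_FILES = (
    "de_results.tsv",
    "module_assignments.tsv",
    "eigenproteins.tsv",
    "kme.tsv",
    "module_trait.tsv",
    "enrichment.tsv",
    "qc_report.json",
    "run_config.json",
)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "genotype", "age_group", "batch", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            genotype=row.genotype,
            age_group=row.age_group,
            batch=row.batch,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def read_abundance(matrix_path: str | Path, sample_sheet_path: str | Path) -> AbundanceMatrix:
    """Read a proteins x samples TSV plus its CSV sample sheet.

    Empty and ``NA``/``NaN`` cells become unquantified entries in the mask.
    Every sample id in the matrix header must appear in the sample sheet.
    """
    samples = read_sample_sheet(sample_sheet_path)
    by_id = {s.sample_id: s for s in samples}
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA", "NaN", ""],
                     float_precision="round_trip")
    header = [str(c) for c in df.columns]
    unknown = [c for c in header if c not in by_id]
    if unknown:
        raise ValueError(f"sample ids in matrix header absent from sample sheet: {unknown}")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate protein ids: {sorted(set(map(str, dup)))}")
    values = df.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    return AbundanceMatrix(
        proteins=[str(p) for p in df.index],
        samples=[by_id[c] for c in header],
        values=values,
        mask=mask,
    )


def write_abundance(matrix: AbundanceMatrix, matrix_path: str | Path,
                    sample_sheet_path: str | Path | None = None) -> None:
    """Inverse of :func:`read_abundance`; masked cells written as empty fields."""
    df = matrix.to_frame()
    df.index.name = "protein"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g", na_rep="")
    if sample_sheet_path is not None:
        matrix.sample_frame().to_csv(sample_sheet_path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read standard GMT: ``name<TAB>description<TAB>member...`` per line.

    Set order is preserved; duplicated members within a line are dropped (one
    logged count per file).  A line with fewer than three fields is fatal.
    """
    sets: dict[str, list[str]] = {}
    n_dupes = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields (need >= 3)")
            name, _desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            n_dupes += len(members) - len(unique)
            sets[name] = unique
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    if n_dupes:
        logger.info("GMT %s: dropped %d duplicated members", path, n_dupes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# canonical headers so empty result tables still round-trip
_EMPTY_COLUMNS = {
    "de_results": ["protein", "contrast", "log2_ratio", "p", "anova_p", "bh_p",
                   "volcano_class"],
    "module_assignments": ["protein", "module", "kme_own", "assigned_via", "n"],
    "eigenproteins": ["module"],
    "kme": ["protein"],
    "module_trait": ["module", "trait", "stratum", "r", "p", "n", "stars"],
    "enrichment": ["kind", "module", "set", "N", "R", "n", "overlap", "fisher_p",
                   "z_score", "bh_p", "stars"],
}


def _write_tsv(df: pd.DataFrame, path: Path, stem: str) -> None:
    if df.empty and len(df.columns) == 0 and stem in _EMPTY_COLUMNS:
        df = pd.DataFrame(columns=_EMPTY_COLUMNS[stem])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_reports(results: dict, out_dir: str | Path) -> dict[str, str]:
    """Persist the full result bundle; returns ``{filename: sha256}``.

    ``results`` maps report names (see :data:`REPORT_FILES` stems) to pandas
    DataFrames or, for the JSON reports, plain dicts.  The file set is fixed
    and deterministic: identical inputs yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for fname in REPORT_FILES:
        stem = fname.rsplit(".", 1)[0]
        obj = results.get(stem)
        path = out / fname
        if fname.endswith(".json"):
            path.write_text(json.dumps(obj if obj is not None else {},
                                       indent=2, sort_keys=True) + "\n")
        else:
            if obj is None:
                obj = pd.DataFrame()
            _write_tsv(obj, path, stem)
        manifest[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest
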