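"""Readers and writers for the package's plain-text interchange formats.

All tabular interchange is TSV with a header row, except methylation
profiles, which use the headerless 5-column BED dialect emitted by
pb-CpG-tools pileups (chrom, start, end, methylation, coverage). CpG sites
serialise as ``chrom:pos``; fragment calls as ``pos:val`` pairs joined with
semicolons. Writers sort rows and fix float formatting so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputFormatError
from .reference import MODEL_COLUMNS, ReferenceAgingModel
from .types import (
    AssignmentResult,
    AtlasSampleSet,
    Fragment,
    MethylationProfile,
    ReferenceAgingDataset,
    sites_index,
)

FLOAT_FMT = "%.6g"


def _parse_site_ids(ids: pd.Series, path: str) -> pd.MultiIndex:
    tuples = []
    for lineno, text in enumerate(ids, start=2):  # header is line 1
        chrom, _, pos = str(text).rpartition(":")
        if not chrom:
            raise InputFormatError(f"{path}:{lineno}: malformed CpG id {text!r}")
        try:
            tuples.append((chrom, int(pos)))
        except ValueError:
            raise InputFormatError(f"{path}:{lineno}: non-integer position in {text!r}")
    return sites_index(tuples)


# ------------------------------------------------------------ reference data
def read_reference(betas_path: str | Path, ages_path: str | Path) -> ReferenceAgingDataset:
    """Sites x samples beta TSV (first column ``cpg`` = chrom:pos) + ages TSV."""
    tab = pd.read_csv(betas_path, sep="\t")
    if tab.shape[1] < 2:
        raise InputFormatError(f"{betas_path}: need a cpg column plus >=1 sample column")
    sites = _parse_site_ids(tab.iloc[:, 0], str(betas_path))
    betas = tab.iloc[:, 1:].set_axis(sites, axis=0).T
    betas.columns = sites
    ages_tab = pd.read_csv(ages_path, sep="\t")
    if not {"sample_id", "age"} <= set(ages_tab.columns):
        raise InputFormatError(f"{ages_path}: expected columns sample_id, age")
    ages = ages_tab.set_index("sample_id")["age"].astype(float)
    missing = [s for s in betas.index if s not in ages.index]
    if missing:
        raise InputFormatError(f"{ages_path}: no age for samples {missing[:5]}")
    return ReferenceAgingDataset(betas=betas, ages=ages.reindex(betas.index))


def write_reference(
    dataset: ReferenceAgingDataset, betas_path: str | Path, ages_path: str | Path
) -> None:
    tab = dataset.betas.T
    out = pd.DataFrame(
        {"cpg": [f"{c}:{p}" for c, p in tab.index]}
    ).join(tab.reset_index(drop=True))
    out.to_csv(betas_path, sep="\t", index=False, float_format=FLOAT_FMT)
    pd.DataFrame({"sample_id": dataset.ages.index, "age": dataset.ages.values}).to_csv(
        ages_path, sep="\t", index=False, float_format=FLOAT_FMT
    )


# -------------------------------------------------------------- fitted model
def write_model(model: ReferenceAgingModel, path: str | Path) -> None:
    tab = model.model_.reset_index()
    tab.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_model(path: str | Path) -> ReferenceAgingModel:
    tab = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", *MODEL_COLUMNS}
    if not required <= set(tab.columns):
        raise InputFormatError(f"{path}: expected columns {sorted(required)}")
    tab = tab.set_index(["chrom", "pos"])
    return ReferenceAgingModel.from_table(tab)


# ----------------------------------------------------------------- profiles
def read_profile_bed(path: str | Path, unit: str = "auto") -> MethylationProfile:
    """Headerless pileup BED: chrom, start, end, methylation, coverage.

    ``unit`` is "fraction" (0-1), "percent" (0-100) or "auto" (percent if
    any value exceeds 1).
    """
    tab = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "meth", "coverage"],
        usecols=range(5),
        comment="#",
    )
    if tab.empty:
        raise InputFormatError(f"{path}: empty profile")
    meth = tab["meth"].astype(float).to_numpy()
    if unit == "auto":
        unit = "percent" if np.nanmax(meth) > 1.0 else "fraction"
    if unit == "percent":
        meth = meth / 100.0
    elif unit != "fraction":
        raise ValueError(f"unknown unit {unit!r}")
    if meth.min() < 0 or meth.max() > 1:
        raise InputFormatError(f"{path}: methylation outside valid range for unit={unit}")
    idx = sites_index(zip(tab["chrom"], tab["start"].astype(int)))
    prof = pd.DataFrame(
        {"beta": meth, "coverage": tab["coverage"].astype(int).to_numpy()}, index=idx
    )
    prof = prof[~prof.index.duplicated()].sort_index()
    return MethylationProfile(beta=prof["beta"], coverage=prof["coverage"])


def write_profile_bed(profile: MethylationProfile, path: str | Path) -> None:
    tab = pd.DataFrame(
        {
            "chrom": profile.sites.get_level_values("chrom"),
            "start": profile.sites.get_level_values("pos"),
            "end": profile.sites.get_level_values("pos") + 2,  # CpG dinucleotide
            "meth": profile.beta.to_numpy(),
            "coverage": profile.coverage.to_numpy(),
        }
    ).sort_values(["chrom", "start"], kind="mergesort")
    tab.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


# -------------------------------------------------------------------- atlas
def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    """Marker atlas TSV: chrom, pos, one mean-beta column per cell type."""
    if atlas.empty:
        raise ValueError("refusing to write an empty atlas")
    tab = atlas.sort_index().reset_index()
    tab.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_atlas(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"} <= set(tab.columns) or tab.shape[1] < 3:
        raise InputFormatError(
            f"{path}: expected chrom, pos plus >=1 cell-type column"
        )
    atlas = tab.set_index(["chrom", "pos"])
    bad = [
        c
        for c in atlas.columns
        if atlas[c].notna().any() and not (0 <= atlas[c].min() and atlas[c].max() <= 1)
    ]
    if bad:
        raise InputFormatError(f"{path}: mean betas outside [0,1] in columns {bad}")
    return atlas


# ------------------------------------------------------------- atlas samples
def write_atlas_samples(samples: AtlasSampleSet, directory: str | Path) -> Path:
    """One TSV per sample (chrom, pos, beta, coverage) + groups.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample_id in samples.betas.index:
        tab = pd.DataFrame(
            {
                "chrom": samples.betas.columns.get_level_values("chrom"),
                "pos": samples.betas.columns.get_level_values("pos"),
                "beta": samples.betas.loc[sample_id].to_numpy(),
                "coverage": samples.coverage.loc[sample_id].to_numpy(),
            }
        )
        tab.to_csv(directory / f"{sample_id}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    groups = pd.DataFrame(
        {"sample_id": samples.labels.index, "cell_type": samples.labels.values}
    )
    groups_path = directory / "groups.tsv"
    groups.to_csv(groups_path, sep="\t", index=False)
    return groups_path


def read_atlas_samples(directory: str | Path, groups_path: str | Path | None = None) -> AtlasSampleSet:
    directory = Path(directory)
    groups_path = Path(groups_path) if groups_path else directory / "groups.tsv"
    groups = pd.read_csv(groups_path, sep="\t")
    if not {"sample_id", "cell_type"} <= set(groups.columns):
        raise InputFormatError(f"{groups_path}: expected columns sample_id, cell_type")
    betas, coverages = {}, {}
    for sample_id in groups["sample_id"]:
        path = directory / f"{sample_id}.tsv"
        if not path.exists():
            raise InputFormatError(f"missing sample file {path}")
        tab = pd.read_csv(path, sep="\t")
        idx = sites_index(zip(tab["chrom"], tab["pos"].astype(int)))
        betas[sample_id] = pd.Series(tab["beta"].to_numpy(dtype=float), index=idx)
        coverages[sample_id] = pd.Series(tab["coverage"].to_numpy(dtype=int), index=idx)
    beta_df = pd.DataFrame(betas).T
    cov_df = pd.DataFrame(coverages).T.reindex(columns=beta_df.columns)
    labels = groups.set_index("sample_id")["cell_type"]
    return AtlasSampleSet(betas=beta_df, coverage=cov_df.fillna(0).astype(int), labels=labels)


# ---------------------------------------------------------------- fragments
def write_fragments(fragments: list[Fragment], path: str | Path) -> None:
    rows = [
        {
            "read_id": f.read_id,
            "chrom": f.chrom,
            "mapq": f.mapq,
            "calls": ";".join(f"{p}:{FLOAT_FMT % v}" for p, v in sorted(f.calls.items())),
        }
        for f in fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> list[Fragment]:
    tab = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    if not {"read_id", "chrom", "mapq", "calls"} <= set(tab.columns):
        raise InputFormatError(f"{path}: expected columns read_id, chrom, mapq, calls")
    fragments = []
    for lineno, row in enumerate(tab.itertuples(index=False), start=2):
        calls: dict[int, float] = {}
        for token in str(row.calls).split(";"):
            pos_s, _, val_s = token.partition(":")
            try:
                pos, val = int(pos_s), float(val_s)
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: malformed call token {token!r} (want pos:val)"
                )
            if not (0.0 <= val <= 1.0):
                raise InputFormatError(
                    f"{path}:{lineno}: call value {val} outside [0, 1]"
                )
            calls[pos] = val
        try:
            fragments.append(
                Fragment(read_id=row.read_id, chrom=row.chrom, mapq=int(row.mapq), calls=calls)
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: {exc}")
    return fragments


# -------------------------------------------------------------- assignments
def write_assignments(results: list[AssignmentResult], path: str | Path) -> None:
    cell_types = sorted({ct for r in results for ct in r.scores})
    rows = []
    for r in results:
        row: dict = {"read_id": r.read_id, "label": r.label, "reason": r.reason or ""}
        for ct in cell_types:
            row[f"L_{ct}"] = r.scores.get(ct, np.nan)
            row[f"n_{ct}"] = r.n_overlap.get(ct, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_assignments(path: str | Path) -> list[AssignmentResult]:
    tab = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    cell_types = [c[2:] for c in tab.columns if c.startswith("L_")]
    results = []
    for row in tab.itertuples(index=False):
        d = row._asdict()
        scores, overlaps = {}, {}
        for ct in cell_types:
            val = d.get(f"L_{ct}", "")
            if val != "":
                scores[ct] = float(val)
            overlaps[ct] = int(d.get(f"n_{ct}", 0) or 0)
        results.append(
            AssignmentResult(
                read_id=str(d["read_id"]),
                label=str(d["label"]),
                scores=scores,
                n_overlap=overlaps,
                reason=str(d["reason"]) or None,
            )
        )
    return results


# -------------------------------------------------------------- predictions
def write_predictions(rows: list[dict], path: str | Path) -> None:
    """Prediction table: sample, n_sites_used, age_estimate [, chronological_age, age_deviation]."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
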