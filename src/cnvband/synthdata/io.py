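"""File formats at the package boundary.

* Per-sample signal TSVs in the PennCNV dialect with header
  ``Name  Chr  Position  Log R Ratio  B Allele Freq``.
* UCSC ``cytoBand.txt`` dialect (0-based half-open), converted to the
  internal 1-based inclusive-start convention on read.
* Covariates as CSV; GMC matrices as dense TSV or (optionally) NIfTI.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .maps import CytobandMap, MarkerMap
from .signals import SampleArray

__all__ = [
    "read_covariates",
    "read_cytoband_file",
    "read_signal_files",
    "write_covariates",
    "write_cytoband_file",
    "write_signal_files",
]

SIGNAL_HEADER = ["Name", "Chr", "Position", "Log R Ratio", "B Allele Freq"]


def write_signal_files(samples: list[SampleArray], marker_map: MarkerMap, directory: str | Path) -> list[Path]:
    """One tab-separated signal file per sample; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in samples:
        path = directory / f"{s.subject_id}.txt"
        df = pd.DataFrame(
            {
                "Name": marker_map.marker_id,
                "Chr": marker_map.chrom,
                "Position": marker_map.position,
                "Log R Ratio": np.round(s.lrr, 6),
                "B Allele Freq": np.round(s.baf, 6),
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        paths.append(path)
    return paths


def read_signal_files(directory: str | Path) -> list[SampleArray]:
    """Read every ``*.txt`` signal file in a directory (sorted by name)."""
    directory = Path(directory)
    samples = []
    for path in sorted(directory.glob("*.txt")):
        samples.append(_read_signal_file(path))
    return samples


def _read_signal_file(path: Path) -> SampleArray:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SIGNAL_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        lrr, baf = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            try:
                lrr.append(float(fields[3]))
                baf.append(float(fields[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric signal value") from exc
    return SampleArray(subject_id=path.stem, lrr=np.asarray(lrr), baf=np.asarray(baf))


def write_cytoband_file(cyto: CytobandMap, path: str | Path) -> Path:
    """Write bands in the UCSC dialect: chrom, 0-based start, end, name, stain."""
    path = Path(path)
    with open(path, "w") as fh:
        for _, r in cyto.bands.iterrows():
            # internal [start, end) 1-based -> UCSC 0-based half-open
            fh.write(f"chr{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end']) - 1}\t{r['name']}\t{r['stain']}\n")
    return path


def read_cytoband_file(path: str | Path, telomere_bp: int = 20_000) -> CytobandMap:
    """Read a UCSC cytoBand file into the internal 1-based convention.

    Centromeres are taken from ``acen``-stained bands; telomeres are
    the first/last ``telomere_bp`` of each chromosome.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            chrom = fields[0].removeprefix("chr")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(fields[1]) + 1,  # UCSC 0-based -> 1-based
                    "end": int(fields[2]) + 1,
                    "name": fields[3],
                    "stain": fields[4],
                }
            )
    bands = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    telomeres: dict[str, list[tuple[int, int]]] = {}
    centromeres: dict[str, tuple[int, int]] = {}
    for chrom, grp in bands.groupby("chrom", sort=False):
        lo, hi = int(grp["start"].min()), int(grp["end"].max())
        telomeres[chrom] = [(lo, lo + telomere_bp), (hi - telomere_bp, hi)]
        acen = grp[grp["stain"] == "acen"]
        if not acen.empty:
            centromeres[chrom] = (int(acen["start"].min()), int(acen["end"].max()))
    return CytobandMap(bands=bands, telomeres=telomeres, centromeres=centromeres)


def write_covariates(subjects: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    subjects.to_csv(path, index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "diagnosis", "age", "gender", "site", "ethnicity", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate file missing columns: {sorted(missing)}")
    if df[sorted(required)].isna().any().any():
        raise ValueError("covariate file contains missing values")
    return df


def write_gmc_matrix(X: np.ndarray, subject_ids: list[str], path: str | Path) -> Path:
    """Dense subjects x voxels matrix as TSV with subject-id index."""
    path = Path(path)
    pd.DataFrame(X, index=subject_ids).to_csv(path, sep="\t", header=False, float_format="%.6g")
    return path


def read_gmc_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_gmc_nifti(X: np.ndarray, shape: tuple[int, int, int], directory: str | Path) -> list[Path]:
    """Optional NIfTI export: each subject row reshaped onto a 3-D lattice."""
    import nibabel as nib  # optional dependency

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if int(np.prod(shape)) != X.shape[1]:
        raise ValueError("lattice shape does not match voxel count")
    paths = []
    for i in range(X.shape[0]):
        img = nib.Nifti1Image(X[i].reshape(shape).astype(np.float32), affine=np.eye(4))
        p = directory / f"gmc_{i:04d}.nii"
        nib.save(img, p)
        paths.append(p)
    return paths
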