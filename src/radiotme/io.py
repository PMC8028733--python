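"""NIfTI / CSV / TSV input-output for the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import DceStudy


def read_study(phase_paths, mask_path, times, lesion_id=None, institution="A") -> DceStudy:
    """Read one 4-phase study (four NIfTI volumes + binary mask).

    All volumes must share grid shape; the voxel spacing is taken from the
    first phase header; the mask may only contain 0/1.
    """
    if len(phase_paths) != 4:
        raise ValueError("exactly 4 phase volumes required (pre + 3 post)")
    imgs = [nib.load(str(p)) for p in phase_paths]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"phase volumes have mismatched shapes: {sorted(shapes)}")
    mask_img = nib.load(str(mask_path))
    if mask_img.shape != imgs[0].shape:
        raise ValueError(
            f"mask shape {mask_img.shape} does not match phases {imgs[0].shape}")
    mask_data = np.asarray(mask_img.dataobj, dtype=float)
    bad = np.setdiff1d(np.unique(mask_data), [0.0, 1.0])
    if bad.size:
        raise ValueError(f"mask contains non-binary values: {bad[:10].tolist()}")
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    phases = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs])
    return DceStudy(
        phases=phases,
        spacing=spacing,
        times=tuple(float(t) for t in times),
        mask=mask_data.astype(bool),
        lesion_id=lesion_id or Path(str(mask_path)).stem,
        institution=institution,
    )


def write_study(study: DceStudy, outdir, prefix=None) -> dict:
    """Write one study as four phase NIfTIs + a mask NIfTI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or study.lesion_id
    affine = np.diag(list(study.spacing) + [1.0])
    paths = {"phases": [], "mask": None}
    for k in range(4):
        p = outdir / f"{prefix}_phase{k}.nii.gz"
        nib.save(nib.Nifti1Image(study.phases[k].astype(np.float32), affine), str(p))
        paths["phases"].append(p)
    mp = outdir / f"{prefix}_mask.nii.gz"
    nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), affine), str(mp))
    paths["mask"] = mp
    return paths


def write_table(df: pd.DataFrame, path, index_label="lesion_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True, index_label=index_label, float_format="%.17g")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Genes-in-rows TSV with a header row of sample IDs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.to_csv(path, sep="\t", index=True, index_label="gene", float_format="%.17g")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(outdir, studies, expr, truth) -> None:
    """Serialize a synthetic cohort: NIfTI studies, expression TSV, and
    ground-truth CSVs."""
    outdir = Path(outdir)
    img_dir = outdir / "images"
    for study in studies:
        write_study(study, img_dir)
    write_expression(expr, outdir / "expression.tsv")
    truth.abundance.to_csv(outdir / "true_abundance.csv", index_label="sample")
    pd.DataFrame({
        "lesion_id": [s.lesion_id for s in studies],
        "amplitude": truth.amplitudes,
    }).to_csv(outdir / "lesion_latents.csv", index=False)
    if truth.realized_correlations:
        rows = [
            {"feature": f, "population": p, "realized_r": r}
            for (f, p), r in truth.realized_correlations.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "realized_correlations.csv", index=False)
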