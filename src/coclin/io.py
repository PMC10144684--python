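"""Readers and writers for the pipeline's on-disk formats.

Primary interchange is NIfTI-1 plus a JSON sidecar carrying the acquisition
axis (``b_values`` in s/mm^2 for diffusion, ``frame_times`` in seconds for
dynamic series). DICOM series directories are supported read-only; per-frame
b-values are taken from the standard diffusion tag when present, otherwise
from a sidecar. Expression tables are plain TSV with a ``gene_symbol`` first
column. A study manifest (JSON) ties subjects, timepoints, series, masks and
expression tables together for the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import __version__
from .errors import InvalidInputError
from .imaging import DiffusionSeries, DynamicSeries, ParameterMap, ROIMask
from .omics import ExpressionMatrix

PathLike = Union[str, Path]


# --------------------------------------------------------------------------
# NIfTI + JSON sidecar
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _spacing_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_series_nifti(
    series: Union[DiffusionSeries, DynamicSeries], path: PathLike
) -> Path:
    """Write a 4-D series as NIfTI-1 float32 with its JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        series.voxels.astype(np.float32), _spacing_affine(series.voxel_spacing)
    )
    nib.save(img, path)
    if isinstance(series, DiffusionSeries):
        sidecar = {"b_values": [float(b) for b in series.b_values]}
    else:
        sidecar = {"frame_times": [float(t) for t in series.frame_times]}
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))
    return path


def read_series_nifti(
    path: PathLike, sidecar: Optional[PathLike] = None
) -> Union[DiffusionSeries, DynamicSeries]:
    """Read a 4-D NIfTI series; the sidecar decides diffusion vs dynamic."""
    path = Path(path)
    sc_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sc_path.exists():
        raise InvalidInputError(f"missing JSON sidecar for {path}: {sc_path}")
    meta = json.loads(sc_path.read_text())
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if "b_values" in meta:
        return DiffusionSeries(
            voxels=data, b_values=np.asarray(meta["b_values"], float),
            voxel_spacing=spacing,
        )
    if "frame_times" in meta:
        return DynamicSeries(
            voxels=data, frame_times=np.asarray(meta["frame_times"], float),
            voxel_spacing=spacing,
        )
    raise InvalidInputError(f"sidecar {sc_path} has neither b_values nor frame_times")


def write_parameter_map(
    pmap: ParameterMap, path: PathLike, extra_provenance: Optional[dict] = None
) -> Path:
    """Write a parameter map as NIfTI-1 float32 (NaN = invalid) + provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        pmap.values.astype(np.float32), _spacing_affine(pmap.voxel_spacing)
    )
    nib.save(img, path)
    prov = {"name": pmap.name, "units": pmap.units, "version": __version__}
    if extra_provenance:
        prov.update(extra_provenance)
    _sidecar_path(path).write_text(json.dumps(prov, sort_keys=True))
    return path


def read_parameter_map(path: PathLike) -> ParameterMap:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    img = nib.load(path)
    return ParameterMap(
        values=np.asanyarray(img.dataobj).astype(float),
        name=meta["name"],
        units=meta["units"],
        voxel_spacing=np.asarray(img.header.get_zooms()[:3], float),
    )


def write_mask_nifti(mask: ROIMask, path: PathLike) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        mask.mask.astype(np.uint8), _spacing_affine(mask.voxel_spacing)
    )
    nib.save(img, path)
    return path


def read_mask_nifti(path: PathLike, label: str = "lesion") -> ROIMask:
    img = nib.load(Path(path))
    return ROIMask(
        mask=np.asanyarray(img.dataobj) > 0,
        voxel_spacing=np.asarray(img.header.get_zooms()[:3], float),
        label=label,
    )


# --------------------------------------------------------------------------
# DICOM series (read; plus a minimal writer for interop and fixtures)
# --------------------------------------------------------------------------

_DIFFUSION_B_TAG = "DiffusionBValue"   # (0018,9087)


def read_dicom_series(
    directory: PathLike, sidecar: Optional[PathLike] = None
) -> Union[DiffusionSeries, DynamicSeries]:
    """Assemble a 4-D series from a directory of single-slice DICOM files.

    All files must share one SeriesInstanceUID. Slices are ordered by their
    z position, frames by the per-frame diffusion b-value tag when present;
    without the tag, a JSON sidecar (``b_values`` or ``frame_times``) names
    the frame axis and files are assigned to frames by InstanceNumber
    (slices varying fastest). File order on disk never matters.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise InvalidInputError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise InvalidInputError(f"mixed SeriesInstanceUIDs in {directory}: {sorted(uids)}")

    spacing_xy = [float(v) for v in datasets[0].PixelSpacing]
    dz = float(getattr(datasets[0], "SpacingBetweenSlices", 0) or
               getattr(datasets[0], "SliceThickness", 1.0))
    spacing = np.array([spacing_xy[0], spacing_xy[1], dz])

    meta = {}
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())

    has_b_tag = all(hasattr(ds, _DIFFUSION_B_TAG) for ds in datasets)
    zpos = sorted({round(float(ds.ImagePositionPatient[2]), 6) for ds in datasets})
    z_index = {z: i for i, z in enumerate(zpos)}
    n_slices = len(zpos)

    if has_b_tag:
        frame_keys = sorted({float(getattr(ds, _DIFFUSION_B_TAG)) for ds in datasets})
        frame_index = {k: i for i, k in enumerate(frame_keys)}
        axis_values = np.asarray(frame_keys, float)
        axis_kind = "b_values"

        def locate(ds):
            return frame_index[float(getattr(ds, _DIFFUSION_B_TAG))]
    else:
        if "b_values" in meta:
            axis_values, axis_kind = np.asarray(meta["b_values"], float), "b_values"
        elif "frame_times" in meta:
            axis_values, axis_kind = np.asarray(meta["frame_times"], float), "frame_times"
        else:
            raise InvalidInputError(
                "DICOM series lacks diffusion b-value tags and no sidecar was given"
            )
        if len(datasets) != n_slices * len(axis_values):
            raise InvalidInputError(
                f"{len(datasets)} files do not factor into {n_slices} slices x "
                f"{len(axis_values)} frames"
            )

        def locate(ds):
            return (int(ds.InstanceNumber) - 1) // n_slices

    n_frames = len(axis_values)
    rows, cols = int(datasets[0].Rows), int(datasets[0].Columns)
    voxels = np.zeros((cols, rows, n_slices, n_frames))
    for ds in datasets:
        zi = z_index[round(float(ds.ImagePositionPatient[2]), 6)]
        fi = locate(ds)
        voxels[:, :, zi, fi] = ds.pixel_array.T.astype(float)

    if axis_kind == "b_values":
        return DiffusionSeries(voxels=voxels, b_values=axis_values, voxel_spacing=spacing)
    return DynamicSeries(voxels=voxels, frame_times=axis_values, voxel_spacing=spacing)


def write_dicom_series(
    series: Union[DiffusionSeries, DynamicSeries],
    directory: PathLike,
    write_b_tags: bool = True,
) -> Path:
    """Write a series as single-slice uint16 DICOM files (interop/testing aid).

    Signal values are rounded to integers; callers needing exact round trips
    should pass integral data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    is_dwi = isinstance(series, DiffusionSeries)
    axis = series.b_values if is_dwi else series.frame_times
    nx, ny, nz, nf = series.voxels.shape
    instance = 0
    for fi in range(nf):
        for zi in range(nz):
            instance += 1
            meta = Dataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = series_uid
            ds.Modality = "MR"
            ds.InstanceNumber = instance
            ds.Rows, ds.Columns = ny, nx
            ds.PixelSpacing = [float(series.voxel_spacing[0]), float(series.voxel_spacing[1])]
            ds.SliceThickness = float(series.voxel_spacing[2])
            ds.ImagePositionPatient = [0.0, 0.0, float(zi * series.voxel_spacing[2])]
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            if is_dwi and write_b_tags:
                ds.DiffusionBValue = float(axis[fi])
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            frame = np.round(series.voxels[:, :, zi, fi]).astype(np.uint16)
            ds.PixelData = frame.T.tobytes()
            ds.save_as(directory / f"slice{instance:04d}.dcm", enforce_file_format=True)
    return directory


# --------------------------------------------------------------------------
# Expression TSV
# --------------------------------------------------------------------------

def read_expression_tsv(
    path: PathLike, cohort: str = "patient", timepoint: str = "T0"
) -> ExpressionMatrix:
    """Parse a gene-by-sample TSV (first column ``gene_symbol``).

    Ragged rows, duplicate gene symbols, and negative or non-numeric values
    raise :class:`InvalidInputError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().rstrip("\n").split("\n")
    if not lines or not lines[0]:
        raise InvalidInputError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    n_cols = len(header)
    symbols: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise InvalidInputError(
                f"{path}:{lineno}: expected {n_cols} fields, found {len(fields)}"
            )
        sym = fields[0]
        if sym in seen:
            raise InvalidInputError(f"{path}:{lineno}: duplicate gene symbol {sym!r}")
        seen.add(sym)
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise InvalidInputError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        if any(v < 0 for v in values):
            raise InvalidInputError(f"{path}:{lineno}: negative expression value")
        symbols.append(sym)
        rows.append(values)
    frame = pd.DataFrame(rows, index=symbols, columns=sample_ids, dtype=float)
    frame.index.name = "gene_symbol"
    return ExpressionMatrix(frame, cohort=cohort, timepoint=timepoint)


def write_expression_tsv(matrix: ExpressionMatrix, path: PathLike) -> Path:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene_symbol")
    return path


# --------------------------------------------------------------------------
# Study manifest
# --------------------------------------------------------------------------

def load_manifest(path: PathLike) -> dict:
    """Load a study manifest and verify every referenced path exists."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    base = path.parent
    for subject in manifest.get("subjects", []):
        sid = subject.get("subject_id", "?")
        for tp, entry in subject.get("timepoints", {}).items():
            if tp not in ("T0", "T1", "T2"):
                raise InvalidInputError(f"subject {sid}: unknown timepoint {tp!r}")
            for key in ("dwi", "dce", "mask"):
                if key not in entry:
                    raise InvalidInputError(
                        f"subject {sid} {tp}: manifest entry missing {key!r}"
                    )
                p = base / entry[key]
                if not p.exists():
                    raise InvalidInputError(f"subject {sid} {tp}: missing file {p}")
    for cohort, p in manifest.get("expression", {}).items():
        if not (base / p).exists():
            raise InvalidInputError(f"expression table for {cohort} missing: {base / p}")
    manifest["_base"] = str(base)
    return manifest


def write_cohort(fixture, directory: PathLike) -> Path:
    """Materialize a :class:`~coclin.phantom.CohortFixture` on disk.

    Writes per-subject, per-timepoint DWI/DCE NIfTI series with sidecars and
    masks, the two baseline expression TSVs, and ``manifest.json`` binding it
    all together (paths relative to the directory).
    """
    from .phantom import TIMEPOINTS, make_dce_phantom, make_dwi_phantom

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects_entries = []
    for truth in fixture.subjects:
        sdir = directory / truth.subject_id
        sdir.mkdir(exist_ok=True)
        tps = {}
        for tp in TIMEPOINTS:
            dwi, mask = make_dwi_phantom(truth, timepoint=tp)
            dce, _ = make_dce_phantom(truth, timepoint=tp)
            dwi_path = sdir / f"{tp}_dwi.nii.gz"
            dce_path = sdir / f"{tp}_dce.nii.gz"
            mask_path = sdir / f"{tp}_mask.nii.gz"
            write_series_nifti(dwi, dwi_path)
            write_series_nifti(dce, dce_path)
            write_mask_nifti(mask, mask_path)
            tps[tp] = {
                "dwi": str(dwi_path.relative_to(directory)),
                "dce": str(dce_path.relative_to(directory)),
                "mask": str(mask_path.relative_to(directory)),
            }
        subjects_entries.append(
            {
                "subject_id": truth.subject_id,
                "cohort": truth.cohort,
                "timepoints": tps,
            }
        )
    expr_paths = {}
    for cohort, matrix in fixture.expression.items():
        p = directory / f"expression_{cohort}_T0.tsv"
        write_expression_tsv(matrix, p)
        expr_paths[cohort] = p.name
    manifest = {
        "version": __version__,
        "seed": fixture.seed,
        "subjects": subjects_entries,
        "expression": expr_paths,
        "planted_genes": {"up": fixture.planted_up, "down": fixture.planted_down},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return directory / "manifest.json"
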