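"""DICOM RT Dose / RT Structure Set import and export.

Lets the pipeline run on real plan exports: an RT Dose grid is converted to
Gy via its DoseGridScaling attribute and structure contours are voxelized to
the dose lattice by per-slice point-in-polygon tests.  Export writes a phantom
back out as a (minimal but standard-conformant) RT Dose / RT Structure Set
pair sharing one frame of reference, which also provides the round-trip
oracle for the importer.

Voxelization unions all contours of a structure on a slice (interior holes
are not subtracted); membership is voxel-center-in-polygon.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .grid import DoseGrid, GridSpec, StructureMask
from .phantom import PatientPhantom

__all__ = ["export_dicom_rt", "import_dicom_rt"]

_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def _file_dataset(path_hint: str, sop_class: str, sop_instance: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(path_hint, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    now = datetime.datetime(2000, 1, 1)  # fixed stamp keeps exports reproducible
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.Modality = "RTDOSE" if sop_class == _RTDOSE_CLASS else "RTSTRUCT"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    return ds


def export_dicom_rt(phantom: PatientPhantom, outdir) -> tuple[Path, Path]:
    """Write ``rtdose.dcm`` and ``rtstruct.dcm`` for a phantom.

    Dose is quantized to uint32 with DoseGridScaling = max_dose / (2^32 - 1);
    every structure mask (brain, GTVs, PTVs, OARs) becomes a set of
    closed-planar contours extracted at the 0.5 iso-level of the mask.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = phantom.grid
    frame_uid = generate_uid()

    # ---- RT Dose: frames along z, rows along y, cols along x
    dose_path = outdir / "rtdose.dcm"
    ds = _file_dataset(str(dose_path), _RTDOSE_CLASS, generate_uid())
    ds.FrameOfReferenceUID = frame_uid
    ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], grid.origin[2]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # row (y), col (x)
    ds.GridFrameOffsetVector = [grid.spacing[2] * k for k in range(grid.shape[2])]
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[0]
    ds.NumberOfFrames = grid.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    dmax = phantom.dose.max
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    quantized = np.round(phantom.dose.values / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(quantized.transpose(2, 1, 0)).tobytes()
    ds.save_as(dose_path, enforce_file_format=True)

    # ---- RT Structure Set
    struct_path = outdir / "rtstruct.dcm"
    ss = _file_dataset(str(struct_path), _RTSTRUCT_CLASS, generate_uid())
    ss.StructureSetLabel = phantom.patient_id
    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ss.ReferencedFrameOfReferenceSequence = [ref_frame]
    ss.StructureSetROISequence = []
    ss.ROIContourSequence = []

    structures: list[StructureMask] = [phantom.brain_mask, *phantom.gtv_masks, *phantom.ptv_masks]
    structures += list(phantom.oar_masks.values())
    z_axis = grid.axes()[2]
    for number, mask in enumerate(structures, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = mask.name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ss.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for k in range(grid.shape[2]):
            sl = mask.voxels[:, :, k]
            if not sl.any():
                continue
            for poly in measure.find_contours(sl.astype(float), 0.5):
                pts = np.empty((len(poly), 3))
                pts[:, 0] = grid.origin[0] + poly[:, 0] * grid.spacing[0]
                pts[:, 1] = grid.origin[1] + poly[:, 1] * grid.spacing[1]
                pts[:, 2] = z_axis[k]
                contour = Dataset()
                contour.ContourGeometricType = "CLOSED_PLANAR"
                contour.NumberOfContourPoints = len(poly)
                contour.ContourData = [round(float(v), 4) for v in pts.ravel()]
                rc.ContourSequence.append(contour)
        ss.ROIContourSequence.append(rc)
    ss.save_as(struct_path, enforce_file_format=True)
    return dose_path, struct_path


def _dose_from_rtdose(ds: pydicom.Dataset) -> DoseGrid:
    if "DoseGridScaling" not in ds:
        raise ValueError("RT Dose is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    if scaling <= 0:
        raise ValueError(f"invalid DoseGridScaling {scaling}")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    if len(offsets) > 1 and not np.allclose(np.diff(offsets), dz):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    ipp = [float(v) for v in ds.ImagePositionPatient]
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), abs(dz))
    arr = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols)
    values = arr.transpose(2, 1, 0)  # -> (x, y, z)
    shape = values.shape
    lo = np.asarray(ipp)
    hi = lo + (np.asarray(shape) - 1) * np.asarray(spacing)
    grid = GridSpec(
        shape=shape, spacing=spacing, origin=tuple(ipp),
        isocenter=tuple((lo + hi) / 2),  # isocenter is not stored in RT Dose
    )
    return DoseGrid(values, grid)


def _voxelize_structset(ds: pydicom.Dataset, grid: GridSpec) -> dict[str, StructureMask]:
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    x_ax, y_ax, z_ax = grid.axes()
    xx, yy = np.meshgrid(x_ax, y_ax, indexing="ij")
    pts2d = np.column_stack([xx.ravel(), yy.ravel()])
    masks: dict[str, StructureMask] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names[int(rc.ReferencedROINumber)]
        vox = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(rc, "ContourSequence", []):
            if contour.ContourGeometricType != "CLOSED_PLANAR":
                continue
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(round((data[0, 2] - grid.origin[2]) / grid.spacing[2]))
            if not 0 <= k < grid.shape[2]:
                continue
            inside = MplPath(data[:, :2]).contains_points(pts2d)
            vox[:, :, k] |= inside.reshape(grid.shape[0], grid.shape[1])
        masks[name] = StructureMask(name, vox, grid)
    return masks


def import_dicom_rt(rtdose_path, rtstruct_path) -> PatientPhantom:
    """Load an RT Dose / RT Structure Set pair onto one lattice.

    Both files must reference the same frame of reference.  Structures named
    ``GTV*``/``PTV*`` populate the per-target mask lists (no analytic target
    specs exist for imported plans), a structure named ``brain`` (any case)
    becomes the brain mask (falling back to the full grid), and everything
    else lands in ``oar_masks``.  Structure names are preserved verbatim.
    """
    dose_ds = pydicom.dcmread(rtdose_path)
    struct_ds = pydicom.dcmread(rtstruct_path)
    dose_frame = getattr(dose_ds, "FrameOfReferenceUID", None)
    struct_frames = {
        getattr(r, "FrameOfReferenceUID", None)
        for r in getattr(struct_ds, "ReferencedFrameOfReferenceSequence", [])
    }
    if dose_frame is None or dose_frame not in struct_frames:
        raise ValueError("RT Dose and RT Structure Set reference different frames")
    dose = _dose_from_rtdose(dose_ds)
    masks = _voxelize_structset(struct_ds, dose.grid)

    brain = None
    gtvs, ptvs, oars = [], [], {}
    for name, mask in masks.items():
        lname = name.lower()
        if lname == "brain":
            brain = mask
        elif lname.startswith("gtv"):
            gtvs.append(mask)
        elif lname.startswith("ptv"):
            ptvs.append(mask)
        else:
            oars[name] = mask
    if brain is None:
        brain = StructureMask("brain", np.ones(dose.grid.shape, dtype=bool), dose.grid)
    return PatientPhantom(
        grid=dose.grid, targets=[], dose=dose, brain_mask=brain,
        gtv_masks=gtvs, ptv_masks=ptvs, oar_masks=oars,
        patient_id=str(getattr(struct_ds, "StructureSetLabel", "imported")),
    )
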