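"""DICOM and NIfTI I/O, DICOM de-identification and CSV report export.

DICOM is the exchange format: CT and PET series are read slice-wise with
the standard rescale to HU (or activity concentration), segmentations are
stored as binary DICOM Segmentation objects, and uploaded studies are
de-identified against a configurable attribute profile modelled on the
DICOM confidentiality profile (remove / dummy / UID-remap actions, with
UIDs remapped consistently within a session so study/series linkage
survives).  NIfTI-1 is the internal interchange format.

Array convention: in-memory volumes are indexed ``[x, y, z]``; DICOM slice
pixel arrays are ``[row=y, col=x]`` and are transposed on the way in/out.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.pixels import pack_bits, unpack_bits
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import ImageGrid, LabelMap, LabelRegistry, Modality, Volume
from .quantify import SuvContext

__all__ = [
    "DicomStudy", "DeidProfile",
    "write_nifti", "read_nifti_volume", "read_nifti_labels",
    "write_ct_series", "read_ct_series",
    "write_pet_series", "read_pet_series",
    "deidentify", "deidentify_directory",
    "write_labelmap_dicom", "read_labelmap_dicom",
    "export_csv",
]

CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
PT_SOP = "1.2.840.10008.5.1.4.1.1.128"
SEG_SOP = "1.2.840.10008.5.1.4.1.1.66.4"


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> ImageGrid:
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    return ImageGrid(tuple(int(n) for n in shape[:3]), spacing,
                     tuple(float(v) for v in aff[:3, 3]))


def write_nifti(obj: Volume | LabelMap, path: str | Path) -> None:
    """Write a Volume (float32) or LabelMap (int32) as NIfTI-1."""
    if isinstance(obj, LabelMap):
        data = obj.labels.astype(np.int32)
    else:
        data = obj.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(obj.grid)), str(path))


def read_nifti_volume(path: str | Path, modality: Modality = Modality.CT_HU) -> Volume:
    img = nib.load(str(path))
    return Volume(_grid_from_affine(img.affine, img.shape),
                  np.asarray(img.dataobj, dtype=np.float64), modality)


def read_nifti_labels(path: str | Path,
                      registry_ref: str = "organseg-catalogue-v1") -> LabelMap:
    img = nib.load(str(path))
    return LabelMap(_grid_from_affine(img.affine, img.shape),
                    np.asarray(img.dataobj).astype(np.int32), registry_ref)


# ---------------------------------------------------------------------------
# DICOM study container
# ---------------------------------------------------------------------------

@dataclass
class DicomStudy:
    """A list of slice datasets (one or more series) plus file bookkeeping."""

    datasets: list[Dataset]

    @classmethod
    def read(cls, directory: str | Path) -> "DicomStudy":
        files = sorted(Path(directory).glob("*.dcm"))
        if not files:
            raise FileNotFoundError(f"no DICOM files in {directory}")
        return cls([pydicom.dcmread(str(f)) for f in files])

    def save(self, directory: str | Path) -> list[Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        out = []
        for i, ds in enumerate(self.datasets):
            p = d / f"{i:05d}.dcm"
            ds.save_as(str(p), enforce_file_format=True)
            out.append(p)
        return out


def _base_dataset(sop_class: str, modality: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    return ds


def _write_slices(volume: Volume, directory: Path, sop_class: str, modality: str,
                  slope: float, intercept: float, extra) -> list[Path]:
    grid = volume.grid
    nx, ny, nz = grid.shape
    sx, sy, sz = grid.spacing
    study_uid, series_uid, frame_uid = generate_uid(), generate_uid(), generate_uid()
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(nz):
        ds = _base_dataset(sop_class, modality)
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{sy:.6f}", f"{sx:.6f}"]
        ds.SliceThickness = f"{sz:.6f}"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [f"{grid.origin[0]:.6f}", f"{grid.origin[1]:.6f}",
                                   f"{grid.origin[2] + k * sz:.6f}"]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{slope:.10g}"
        ds.RescaleIntercept = f"{intercept:.10g}"
        stored = np.round((volume.values[:, :, k] - intercept) / slope)
        ds.PixelData = np.clip(stored, 0, 65535).astype(np.uint16).T.tobytes()
        for key, val in extra.items():
            setattr(ds, key, val)
        p = directory / f"slice{k:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


def write_ct_series(volume: Volume, directory: str | Path,
                    patient_name: str = "Phantom^Test",
                    patient_id: str = "PH-0001") -> list[Path]:
    """Write a CT volume (HU) as a DICOM series (slope 1, intercept -1024)."""
    if volume.modality is not Modality.CT_HU:
        raise ValueError("write_ct_series expects a CT volume")
    extra = {"PatientName": patient_name, "PatientID": patient_id,
             "StudyDate": "20200101", "SeriesDate": "20200101",
             "PatientBirthDate": "19600101"}
    # adaptive intercept so very low HU (air minus noise) is not clipped
    intercept = min(-1024.0, float(np.floor(volume.values.min())))
    return _write_slices(volume, Path(directory), CT_SOP, "CT",
                         1.0, intercept, extra)


def read_ct_series(directory: str | Path) -> Volume:
    """Read one CT series back into a HU volume.

    Slices are sorted by z position regardless of file order; mixed series
    or missing geometry tags raise.
    """
    arr, grid, _ = _read_series(directory, expected_modality="CT")
    return Volume(grid, arr, Modality.CT_HU)


def _read_series(directory, expected_modality=None):
    study = DicomStudy.read(directory)
    series_uids = {ds.SeriesInstanceUID for ds in study.datasets}
    if len(series_uids) != 1:
        raise ValueError(f"directory contains {len(series_uids)} series; expected one")
    slices = study.datasets
    for ds in slices:
        for tag in ("ImagePositionPatient", "PixelSpacing"):
            if tag not in ds:
                raise ValueError(f"slice missing geometry tag {tag}")
        if expected_modality and ds.Modality != expected_modality:
            raise ValueError(f"expected {expected_modality} series, got {ds.Modality}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    nz = len(slices)
    first = slices[0]
    ny, nx = int(first.Rows), int(first.Columns)
    sy, sx = (float(v) for v in first.PixelSpacing)
    if nz > 1:
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise ValueError("duplicate or unordered slice positions")
        if not np.allclose(dz, dz[0], rtol=1e-4):
            raise ValueError("non-uniform slice spacing")
        sz = float(dz[0])
    else:
        sz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    grid = ImageGrid((nx, ny, nz), (sx, sy, sz), origin)
    arr = np.empty((nx, ny, nz), dtype=np.float64)
    for k, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr[:, :, k] = ds.pixel_array.T * slope + intercept
    return arr, grid, slices


def write_pet_series(volume: Volume, directory: str | Path,
                     context: SuvContext,
                     patient_name: str = "Phantom^Test",
                     patient_id: str = "PH-0001") -> list[Path]:
    """Write a PET volume (kBq/ml) as a DICOM PT series in BQML units.

    Radiopharmaceutical metadata (dose, half-life, injection-to-scan delay)
    and the patient weight are embedded so SUV can be recomputed on read.
    """
    if volume.modality is not Modality.PET_ACTIVITY:
        raise ValueError("write_pet_series expects a PET activity volume")
    bqml = volume.values * 1000.0  # kBq/ml -> Bq/ml
    vmax = max(float(bqml.max()), 1.0)
    slope = vmax / 60000.0
    radio = Dataset()
    radio.RadionuclideTotalDose = f"{context.injected_dose_bq:.10g}"
    radio.RadionuclideHalfLife = f"{context.half_life_s:.10g}"
    start = (datetime.datetime(2020, 1, 1, 10, 0, 0)
             - datetime.timedelta(seconds=context.injection_to_scan_s))
    radio.RadiopharmaceuticalStartTime = start.strftime("%H%M%S.%f")
    extra = {
        "PatientName": patient_name, "PatientID": patient_id,
        "Units": "BQML", "PatientWeight": f"{context.patient_weight_kg:.6g}",
        "SeriesTime": "100000.000000", "AcquisitionTime": "100000.000000",
        "DecayCorrection": "START",
        "RadiopharmaceuticalInformationSequence": [radio],
    }
    scaled = Volume(volume.grid, bqml, Modality.PET_ACTIVITY)
    return _write_slices(scaled, Path(directory), PT_SOP, "PT", slope, 0.0, extra)


def read_pet_series(directory: str | Path) -> tuple[Volume, SuvContext]:
    """Read a PET series into a kBq/ml volume plus its SUV context."""
    arr, grid, slices = _read_series(directory, expected_modality="PT")
    ds = slices[0]
    units = getattr(ds, "Units", "BQML")
    if units != "BQML":
        raise ValueError(f"unsupported PET units {units!r}")
    try:
        radio = ds.RadiopharmaceuticalInformationSequence[0]
        dose = float(radio.RadionuclideTotalDose)
        half_life = float(radio.RadionuclideHalfLife)
        inj_time = _parse_tm(str(radio.RadiopharmaceuticalStartTime))
        scan_time = _parse_tm(str(ds.SeriesTime))
        weight = float(ds.PatientWeight)
    except (AttributeError, IndexError, KeyError) as exc:
        raise ValueError("PET series lacks radiopharmaceutical metadata") from exc
    delay = (scan_time - inj_time).total_seconds() % (24 * 3600)
    context = SuvContext(injected_dose_bq=dose, patient_weight_kg=weight,
                         half_life_s=half_life, injection_to_scan_s=delay,
                         stored_units="KBQML")
    return Volume(grid, arr / 1000.0, Modality.PET_ACTIVITY), context


def _parse_tm(tm: str) -> datetime.datetime:
    tm = tm.split(".")[0].ljust(6, "0")
    frac = 0.0
    return datetime.datetime(2020, 1, 1, int(tm[:2]), int(tm[2:4]), int(tm[4:6]))


# ---------------------------------------------------------------------------
# de-identification
# ---------------------------------------------------------------------------

#: attribute -> action. Subset of the DICOM confidentiality profile's
#: identifying attributes relevant to CT/PT/SEG objects.
_DEFAULT_ACTIONS = {
    "PatientName": "dummy",
    "PatientID": "dummy",
    "PatientBirthDate": "remove",
    "PatientBirthTime": "remove",
    "PatientAddress": "remove",
    "PatientTelephoneNumbers": "remove",
    "OtherPatientIDs": "remove",
    "OtherPatientNames": "remove",
    "ReferringPhysicianName": "dummy",
    "PerformingPhysicianName": "remove",
    "PhysiciansOfRecord": "remove",
    "OperatorsName": "remove",
    "InstitutionName": "remove",
    "InstitutionAddress": "remove",
    "StationName": "remove",
    "DeviceSerialNumber": "remove",
    "AccessionNumber": "dummy",
    "StudyID": "dummy",
    "StudyDate": "dummy",
    "SeriesDate": "dummy",
    "AcquisitionDate": "dummy",
    "ContentDate": "dummy",
    "StudyTime": "dummy",
    "SeriesTime": "keep",        # needed for SUV decay correction
    "AcquisitionTime": "keep",
    "PatientWeight": "keep",     # needed for SUVbw
    "StudyInstanceUID": "remap",
    "SeriesInstanceUID": "remap",
    "SOPInstanceUID": "remap",
    "FrameOfReferenceUID": "remap",
}

_DUMMIES = {"PN": "ANONYMIZED", "DA": "19000101", "TM": "000000",
            "SH": "ANON", "LO": "ANON"}


@dataclass
class DeidProfile:
    """Attribute actions for de-identification.

    ``actions`` maps DICOM keyword -> one of remove / dummy / remap / keep.
    UID remapping is a consistent injection within one profile instance
    (the "session"): the same input UID always maps to the same fresh UID,
    so series/study linkage is preserved.  Private tags are always removed.
    """

    actions: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_ACTIONS))
    uid_map: dict[str, str] = field(default_factory=dict)

    def remap_uid(self, old: str) -> str:
        if old not in self.uid_map:
            self.uid_map[old] = generate_uid()
        return self.uid_map[old]


def _apply_action(ds: Dataset, keyword: str, action: str, profile: DeidProfile) -> None:
    if keyword not in ds:
        return
    if action == "keep":
        return
    if action == "remove":
        delattr(ds, keyword)
        return
    elem = ds[keyword]
    if action == "dummy":
        elem.value = _DUMMIES.get(elem.VR, "ANON")
    elif action == "remap":
        elem.value = profile.remap_uid(str(elem.value))
    else:
        raise ValueError(f"unknown de-identification action {action!r}")


def deidentify(study: DicomStudy, profile: DeidProfile | None = None) -> DicomStudy:
    """De-identify every dataset of a study according to the profile.

    Pixel data is untouched.  Applying the function twice is a no-op on
    attribute values up to the UID remapping session (dummies stay
    dummies; UIDs are remapped again, consistently).
    """
    import copy

    profile = profile or DeidProfile()
    out = []
    for ds in study.datasets:
        ds = copy.deepcopy(ds)  # Dataset.copy() is shallow; never mutate the input
        ds.remove_private_tags()
        for keyword, action in profile.actions.items():
            _apply_action(ds, keyword, action, profile)
        if "file_meta" in dir(ds) and ds.file_meta is not None:
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.PatientIdentityRemoved = "YES"
        ds.DeidentificationMethod = "organseg attribute profile v1"
        out.append(ds)
    return DicomStudy(out)


def deidentify_directory(in_dir: str | Path, out_dir: str | Path,
                         profile: DeidProfile | None = None) -> list[Path]:
    study = deidentify(DicomStudy.read(in_dir), profile)
    return study.save(out_dir)


# ---------------------------------------------------------------------------
# DICOM Segmentation storage
# ---------------------------------------------------------------------------

def write_labelmap_dicom(labels: LabelMap, registry: LabelRegistry,
                         path: str | Path) -> Path:
    """Store a label map as a binary DICOM Segmentation object.

    One binary frame per (segment, slice); segment numbers are 1..n in
    ascending registry-label order, with the registry label index kept in
    SegmentDescription and the organ name in SegmentLabel, so the
    round-trip reproduces both the array and the names exactly.
    """
    grid = labels.grid
    nx, ny, nz = grid.shape
    present = labels.present_labels()
    ds = _base_dataset(SEG_SOP, "SEG")
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.Rows, ds.Columns = ny, nx
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 1
    ds.BitsStored = 1
    ds.HighBit = 0
    ds.PixelRepresentation = 0
    ds.SegmentationType = "BINARY"
    ds.ContentLabel = "ORGANSEG"
    ds.LossyImageCompression = "00"
    ds.PixelSpacing = [f"{grid.spacing[1]:.6f}", f"{grid.spacing[0]:.6f}"]
    ds.SpacingBetweenSlices = f"{grid.spacing[2]:.6f}"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [f"{v:.6f}" for v in grid.origin]
    ds.NumberOfSlices = nz  # keeps the z extent recoverable when no segment is present

    segments = []
    for num, lab in enumerate(present, start=1):
        seg = Dataset()
        seg.SegmentNumber = num
        seg.SegmentLabel = registry[lab].name if lab in registry else str(lab)
        seg.SegmentDescription = str(lab)
        seg.SegmentAlgorithmType = "AUTOMATIC"
        seg.SegmentAlgorithmName = "organseg"
        segments.append(seg)
    ds.SegmentSequence = segments

    frames = []
    perframe = []
    for num, lab in enumerate(present, start=1):
        mask = labels.labels == lab
        for k in range(nz):
            frames.append(mask[:, :, k].T)
            fg = Dataset()
            ident = Dataset()
            ident.ReferencedSegmentNumber = num
            fg.SegmentIdentificationSequence = [ident]
            pos = Dataset()
            pos.ImagePositionPatient = [
                f"{grid.origin[0]:.6f}", f"{grid.origin[1]:.6f}",
                f"{grid.origin[2] + k * grid.spacing[2]:.6f}"]
            fg.PlanePositionSequence = [pos]
            perframe.append(fg)
    ds.NumberOfFrames = len(frames)
    ds.PerFrameFunctionalGroupsSequence = perframe
    if frames:
        ds.PixelData = pack_bits(np.concatenate([f.ravel() for f in frames]))
    else:
        ds.PixelData = b""
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_labelmap_dicom(path: str | Path,
                        registry_ref: str = "organseg-catalogue-v1"
                        ) -> tuple[LabelMap, dict[int, str]]:
    """Inverse of :func:`write_labelmap_dicom`: label array + names."""
    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != SEG_SOP:
        raise ValueError("not a DICOM Segmentation object")
    ny, nx = int(ds.Rows), int(ds.Columns)
    sy, sx = (float(v) for v in ds.PixelSpacing)
    sz = float(ds.SpacingBetweenSlices)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    nframes = int(getattr(ds, "NumberOfFrames", 0))
    seg_label = {}
    seg_name = {}
    for seg in ds.SegmentSequence:
        num = int(seg.SegmentNumber)
        seg_label[num] = int(seg.SegmentDescription)
        seg_name[seg_label[num]] = str(seg.SegmentLabel)
    zs = sorted({float(fg.PlanePositionSequence[0].ImagePositionPatient[2])
                 for fg in ds.PerFrameFunctionalGroupsSequence}) if nframes else []
    nz = len(zs) if zs else int(getattr(ds, "NumberOfSlices", 1))
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    if nframes:
        bits = unpack_bits(ds.PixelData)[: nframes * ny * nx]
        frames = bits.reshape(nframes, ny, nx).astype(bool)
        z_index = {z: i for i, z in enumerate(zs)}
        for i, fg in enumerate(ds.PerFrameFunctionalGroupsSequence):
            num = int(fg.SegmentIdentificationSequence[0].ReferencedSegmentNumber)
            z = float(fg.PlanePositionSequence[0].ImagePositionPatient[2])
            labels[:, :, z_index[z]][frames[i].T] = seg_label[num]
    grid = ImageGrid((nx, ny, nz), (sx, sy, sz), origin)
    return LabelMap(grid, labels, registry_ref), seg_name


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def export_csv(report: pd.DataFrame, path: str | Path) -> Path:
    """Write a quantification/metrics table as locale-independent CSV.

    Full float precision is kept so a re-parse reproduces the source
    values.
    """
    if report.columns.empty:
        raise ValueError("report has no columns")
    path = Path(path)
    report.to_csv(path, index=False)
    return path
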