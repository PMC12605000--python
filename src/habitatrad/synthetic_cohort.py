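"""Synthetic multi-sequence lesion cohorts with known habitat structure.

Each simulated patient carries one spinal-metastasis-like lesion imaged in two
MRI-like sequences (T1W-like and T2FS-like).  The lesion is an ellipsoid whose
core ("inner habitat", S2) has a higher mean intensity and a rougher local
texture than the surrounding shell ("marginal habitat", S1).  Label-positive
patients additionally receive a perturbation of the inner-habitat texture
parameters only, so the class signal is spatially concentrated where the
downstream subregion models expect it.  Scanner batch effects are applied as a
per-batch additive shift and multiplicative scale after class effects, the
location-scale family ComBat is designed to remove.

Texture roughness is induced by spatially correlated Gaussian fields: white
noise smoothed in-plane with a habitat-specific Gaussian correlation length.
Shorter correlation lengths give rougher fields and hence higher local
entropy, which gives direct, monotone control of the entropy gap between
habitats without committing to a biological model.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

# In-plane window that the entropy stage slides over the lesion; the inner
# habitat must be able to contain it.
ENTROPY_WINDOW = 9

# Base in-plane correlation length (voxels) of the marginal-habitat field.
_BASE_SIGMA = 1.4

SEQUENCES = ("T1W", "T2FS")

# The second sequence shares habitat geometry but has distinct contrasts.
_T2FS_CONTRAST_FACTOR = 0.8


@dataclass
class BatchEffect:
    """Scanner batch: additive shift and multiplicative scale on intensities."""

    name: str
    shift: float = 0.0
    scale: float = 1.0


def _default_batches() -> list[BatchEffect]:
    return [
        BatchEffect("scanner1", 0.0, 1.0),
        BatchEffect("scanner2", 0.5, 1.2),
    ]


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    ``habitat_contrast`` is the intensity mean gap between the inner and
    marginal habitat in units of the voxel SD (``noise_sd``);
    ``entropy_contrast`` controls how much rougher the inner-habitat field is
    (0 means identical texture); ``class_effect`` scales the perturbation of
    inner-habitat texture in label-positive patients.  The last batch in
    ``batch_ids`` plays the role of the external center.
    """

    n_patients: int = 60
    prevalence: float = 0.45
    n_slices: int = 4
    height: int = 96
    width: int = 96
    habitat_contrast: float = 3.0
    entropy_contrast: float = 2.5
    class_effect: float = 0.75
    batch_ids: list[BatchEffect] = field(default_factory=_default_batches)
    noise_sd: float = 1.0
    seed: int = 0
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0)
    scattered: bool = False
    external_fraction: float = 0.27

    def validate(self) -> None:
        if min(self.height, self.width) < ENTROPY_WINDOW:
            raise ValueError(
                f"in-plane dims must be >= {ENTROPY_WINDOW} (entropy window); "
                f"got {self.height}x{self.width}"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.prevalence * self.n_patients < 2 or (1 - self.prevalence) * self.n_patients < 2:
            raise ValueError("expected class counts must both be >= 2")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.batch_ids) < 1:
            raise ValueError("at least one batch required")
        # The inner habitat must fit the entropy window in-plane.
        r_in = 0.62 * 0.20 * min(self.height, self.width)
        if 2 * r_in < ENTROPY_WINDOW:
            raise ValueError(
                "grid too small: the inner habitat cannot contain a "
                f"{ENTROPY_WINDOW}x{ENTROPY_WINDOW} in-plane window"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["batch_ids"] = [dataclasses.asdict(b) for b in self.batch_ids]
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "batch_ids" in d:
            d["batch_ids"] = [
                BatchEffect(**b) if isinstance(b, dict) else b for b in d["batch_ids"]
            ]
        if "spacing" in d:
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)


@dataclass
class LesionVolume:
    """One sequence's image and lesion mask for one patient."""

    patient_id: str
    sequence_id: str
    image: np.ndarray  # (z, y, x) float
    mask: np.ndarray  # (z, y, x) bool
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.image = np.asarray(self.image, dtype=float)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask grids disagree")
        if not self.mask.any():
            raise ValueError(f"empty lesion mask for {self.patient_id}/{self.sequence_id}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("non-finite intensities")


@dataclass
class Cohort:
    """All lesions, the clinical table, and ground-truth habitat labels."""

    spec: CohortSpec
    volumes: dict[tuple[str, str], LesionVolume]  # (patient_id, sequence_id)
    clinical: pd.DataFrame  # indexed by patient_id
    habitat_truth: dict[str, np.ndarray]  # 0 bg, 1 marginal, 2 inner

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical.index)

    def volume(self, patient_id: str, sequence_id: str) -> LesionVolume:
        return self.volumes[(patient_id, sequence_id)]


def _ellipsoid(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def _correlated_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """In-plane smoothed unit-variance Gaussian field."""
    noise = rng.standard_normal(shape)
    if sigma <= 0:
        return noise
    sm = ndimage.gaussian_filter(noise, sigma=(0.0, sigma, sigma), mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _lesion_geometry(rng: np.random.Generator, spec: CohortSpec):
    """Ellipsoidal lesion with a nested (or scattered) inner habitat."""
    shape = (spec.n_slices, spec.height, spec.width)
    r_in_plane = min(spec.height, spec.width)
    ry = rng.uniform(0.20, 0.28) * r_in_plane
    rx = rng.uniform(0.20, 0.28) * r_in_plane
    rz = 2.0 * spec.n_slices  # near-cylindrical through-slice profile
    cy = spec.height / 2.0 + rng.uniform(-2, 2)
    cx = spec.width / 2.0 + rng.uniform(-2, 2)
    cz = (spec.n_slices - 1) / 2.0
    lesion = _ellipsoid(shape, (cz, cy, cx), (rz, ry, rx))

    f = rng.uniform(0.50, 0.62)  # inner/outer semi-axis ratio
    if 2 * f * min(ry, rx) < ENTROPY_WINDOW:
        raise ValueError(
            "inner habitat cannot contain the "
            f"{ENTROPY_WINDOW}x{ENTROPY_WINDOW} entropy window (in-plane "
            f"radius {f * min(ry, rx):.1f} voxels)"
        )
    if spec.scattered:
        blob = ndimage.gaussian_filter(rng.standard_normal(shape), (0, 3.0, 3.0))
        vals = blob[lesion]
        thr = np.quantile(vals, 1.0 - f**2)
        inner = lesion & (blob >= thr)
    else:
        inner = _ellipsoid(shape, (cz, cy, cx), (max(rz * f, 0.5), ry * f, rx * f)) & lesion

    frac = inner.sum() / lesion.sum()
    if not 0.2 <= frac <= 0.8:
        # re-threshold scattered mode; concentric geometry keeps 0.2-0.8 by
        # construction of f, up to voxelization on tiny grids
        if spec.scattered:
            vals = blob[lesion]
            thr = np.quantile(vals, 0.55)
            inner = lesion & (blob >= thr)
    return lesion, inner


def _render_sequence(
    rng: np.random.Generator,
    spec: CohortSpec,
    lesion: np.ndarray,
    inner: np.ndarray,
    label: int,
    contrast_factor: float,
    patient_texture_factor: float = 1.0,
) -> np.ndarray:
    """Synthesize one sequence's intensities for one patient.

    ``patient_texture_factor`` is a patient-level multiplier shared across
    sequences; an additional per-sequence lognormal jitter is drawn here.
    Together they emulate between-patient biological variability, without
    which any consistent class effect would be perfectly separable.
    """
    shape = lesion.shape
    hc = spec.habitat_contrast * contrast_factor
    ec = spec.entropy_contrast * contrast_factor
    sd = spec.noise_sd

    sigma_marginal = _BASE_SIGMA * np.exp(rng.normal(0.0, 0.08))
    sigma_inner = _BASE_SIGMA / (1.0 + ec) * np.exp(rng.normal(0.0, 0.08))
    amp_marginal = 0.7 * sd * np.exp(rng.normal(0.0, 0.10))
    # a rougher AND wider-histogram core: both raise local entropy
    amp_inner = (
        0.7 * sd * (1.0 + 0.25 * ec)
        * patient_texture_factor
        * np.exp(rng.normal(0.0, 0.15))
    )
    field_m = _correlated_field(rng, shape, sigma_marginal) * amp_marginal
    field_i = _correlated_field(rng, shape, sigma_inner) * amp_inner
    if label == 1 and spec.class_effect > 0:
        # class signal lives in the inner habitat's texture only: a slow
        # multiplicative modulation makes the core patchy (nonuniform local
        # variance) while the global normalization keeps the ROI-level
        # second moment unchanged, so marginal-region features stay clean
        depth = 0.5 * spec.class_effect
        g = _correlated_field(rng, shape, 4.0)
        field_i = field_i * (1.0 + depth * g) / np.sqrt(1.0 + depth**2)

    # partial-volume style transition: the inner habitat blends into the
    # margin over ~1 voxel, as at real tissue interfaces, instead of a
    # step edge (whose bimodal windows would carry spurious entropy)
    w_in = ndimage.gaussian_filter(inner.astype(float), sigma=(0.0, 1.0, 1.0))
    img = rng.standard_normal(shape) * 0.1 * sd  # faint background
    les = 10.0 + hc * sd * w_in + (1.0 - w_in) * field_m + w_in * field_i
    img[lesion] = les[lesion]
    return img


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort of two-sequence lesions with known habitat truth.

    Returns lesions for both sequences, a clinical table (age, gender,
    smoking, PS score, CEA, CYFRA, NSE, label, split, batch) and the
    ground-truth habitat label volume per patient (1 marginal, 2 inner).
    Identical specs (including seed) produce bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_patients
    labels = (rng.random(n) < spec.prevalence).astype(int)
    # guarantee both classes (analysis is undefined otherwise)
    if labels.sum() < 2:
        labels[:2] = 1
    if (1 - labels).sum() < 2:
        labels[-2:] = 0

    n_batches = len(spec.batch_ids)
    if n_batches == 1:
        batch_idx = np.zeros(n, dtype=int)
    else:
        p_ext = spec.external_fraction
        probs = [(1 - p_ext) / (n_batches - 1)] * (n_batches - 1) + [p_ext]
        batch_idx = rng.choice(n_batches, size=n, p=probs)
    batch_names = np.array([b.name for b in spec.batch_ids])[batch_idx]

    # splits: last batch is the external center; remaining patients are split
    # train:internal at 2:1 stratified by label
    split = np.empty(n, dtype=object)
    external = batch_idx == (n_batches - 1) if n_batches > 1 else np.zeros(n, dtype=bool)
    split[external] = "external"
    for lab in (0, 1):
        idx = np.flatnonzero(~external & (labels == lab))
        idx = rng.permutation(idx)
        n_train = int(round(len(idx) * 2 / 3))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "internal"

    volumes: dict[tuple[str, str], LesionVolume] = {}
    habitat_truth: dict[str, np.ndarray] = {}
    rows = []
    for i in range(n):
        pid = f"P{i:03d}"
        lab = int(labels[i])
        batch = spec.batch_ids[batch_idx[i]]
        geo_rng = np.random.default_rng([spec.seed, i, 7])
        lesion, inner = _lesion_geometry(geo_rng, spec)
        tex_factor = float(np.exp(geo_rng.normal(0.0, 0.10)))
        truth = np.zeros(lesion.shape, dtype=np.int16)
        truth[lesion] = 1
        truth[inner] = 2
        habitat_truth[pid] = truth
        for s, seq in enumerate(SEQUENCES):
            seq_rng = np.random.default_rng([spec.seed, i, s])
            cf = 1.0 if seq == "T1W" else _T2FS_CONTRAST_FACTOR
            img = _render_sequence(seq_rng, spec, lesion, inner, lab, cf, tex_factor)
            img = batch.shift + batch.scale * img  # batch after class effects
            volumes[(pid, seq)] = LesionVolume(pid, seq, img, lesion, spec.spacing)

        clin_rng = np.random.default_rng([spec.seed, i, 99])
        smoking_p = 0.45 if lab == 1 else 0.10
        rows.append(
            {
                "patient_id": pid,
                "age": float(np.round(clin_rng.normal(60.0, 9.5), 1)),
                "gender": "female" if clin_rng.random() < 0.6 else "male",
                "smoking": int(clin_rng.random() < smoking_p),
                "ps_score": int(clin_rng.choice([0, 1, 2], p=[0.15, 0.75, 0.10])),
                "cea": float(np.round(clin_rng.lognormal(3.5, 1.2), 2)),
                "cyfra": float(np.round(clin_rng.lognormal(1.6, 0.9), 2)),
                "nse": float(np.round(clin_rng.lognormal(2.9, 0.6), 2)),
                "label": lab,
                "split": split[i],
                "batch": batch_names[i],
            }
        )

    clinical = pd.DataFrame(rows).set_index("patient_id")
    return Cohort(spec=spec, volumes=volumes, clinical=clinical, habitat_truth=habitat_truth)


# ---------------------------------------------------------------------------
# I/O: NIfTI images/masks, CSV clinical table, JSON manifest
# ---------------------------------------------------------------------------


def _affine(spacing) -> np.ndarray:
    # arrays are (z, y, x); store with voxel sizes on the diagonal
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def write_cohort(cohort: Cohort, directory: str | Path) -> dict:
    """Write NIfTI image+mask per patient-sequence, clinical CSV, manifest.

    Returns the manifest (also written as ``manifest.json``); the written
    tree round-trips losslessly through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {"images": {}, "masks": {}, "truth": {}}
    try:
        for (pid, seq), vol in cohort.volumes.items():
            img_p = directory / f"{pid}_{seq}_image.nii.gz"
            msk_p = directory / f"{pid}_{seq}_mask.nii.gz"
            aff = _affine(vol.spacing)
            nib.save(nib.Nifti1Image(np.transpose(vol.image, (2, 1, 0)), aff), img_p)
            nib.save(
                nib.Nifti1Image(np.transpose(vol.mask.astype(np.uint8), (2, 1, 0)), aff), msk_p
            )
            files["images"][f"{pid}|{seq}"] = img_p.name
            files["masks"][f"{pid}|{seq}"] = msk_p.name
        for pid, truth in cohort.habitat_truth.items():
            tp = directory / f"{pid}_habitat_truth.nii.gz"
            nib.save(
                nib.Nifti1Image(np.transpose(truth.astype(np.int16), (2, 1, 0)), _affine(cohort.spec.spacing)),
                tp,
            )
            files["truth"][pid] = tp.name
        clin_p = directory / "clinical.csv"
        cohort.clinical.to_csv(clin_p)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc

    manifest = {
        "spec": cohort.spec.to_dict(),
        "clinical": clin_p.name,
        "files": files,
        "seed": cohort.spec.seed,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = CohortSpec.from_dict(manifest["spec"])
    clinical = pd.read_csv(directory / manifest["clinical"], index_col="patient_id")
    volumes = {}
    for key, name in manifest["files"]["images"].items():
        pid, seq = key.split("|")
        img = np.transpose(np.asarray(nib.load(directory / name).dataobj, dtype=float), (2, 1, 0))
        mname = manifest["files"]["masks"][key]
        mask = np.transpose(np.asarray(nib.load(directory / mname).dataobj), (2, 1, 0)) > 0
        volumes[(pid, seq)] = LesionVolume(pid, seq, img, mask, tuple(spec.spacing))
    truth = {}
    for pid, name in manifest["files"]["truth"].items():
        truth[pid] = np.transpose(
            np.asarray(nib.load(directory / name).dataobj, dtype=np.int16), (2, 1, 0)
        )
    return Cohort(spec=spec, volumes=volumes, clinical=clinical, habitat_truth=truth)
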