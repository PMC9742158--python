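"""Synthetic multi-subject brain phantoms with known microstructure.

A phantom is a voxel grid partitioned into z-slabs of tissue classes.
Fan classes hold 20 straight mini-bundles whose axes sweep the
fibre-to-field angle range at the angular-bin centres (2.25, 6.75, ...,
87.75 degrees), so that every 4.5-degree bin of the downstream analysis
is populated with an equal number of voxels per class.  Each class has a
Watson orientation dispersion, stick/zeppelin diffusivities, and an
angular T1 law ``T1(theta) = t1_base + peak_amp * gauss(theta) +
grad_amp * (1 - theta / 90)`` evaluated at the true bundle angle.

Diffusion signals are produced from Watson-averaged tensors (axial
second moment by exact quadrature), inversion-recovery series from the
magnitude mono-exponential model, and both get Rician noise.  All
randomness flows from the scenario seed through named substreams, so a
given (scenario, subject) pair is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datasets import DWIDataset
from .orientation import fibre_to_field_angle, odi_from_kappa
from .watson import cos2_moment, kappa_from_cos2, scatter_matrix

__all__ = [
    "AngularT1Law",
    "TissueClass",
    "ScenarioConfig",
    "PhantomLayout",
    "fan_angles",
    "build_layout",
    "build_truth",
    "fibonacci_hemisphere",
    "gradient_table",
    "rician",
    "simulate_dwi",
    "simulate_ir",
    "export_ground_truth",
]

# substream codes for per-subject random streams
_STREAM_DWI = 0
_STREAM_IR = 1
_STREAM_LAW = 2

N_FAN = 20


def fan_angles() -> np.ndarray:
    """Nominal bundle angles of a fan class: the 20 angular-bin centres."""
    return (np.arange(N_FAN) + 0.5) * 4.5


@dataclass(frozen=True)
class AngularT1Law:
    """T1 as a function of the fibre-to-field angle (degrees, ms)."""

    t1_base: float
    peak_amp: float = 0.0
    theta_peak: float = 54.0
    sigma_peak: float = 12.0
    grad_amp: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.theta_peak <= 90.0:
            raise ValueError("theta_peak must lie in [0, 90] degrees")
        if self.sigma_peak <= 0:
            raise ValueError("sigma_peak must be > 0")

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = (
            self.t1_base
            + self.peak_amp * np.exp(-((theta - self.theta_peak) ** 2) / (2.0 * self.sigma_peak ** 2))
            + self.grad_amp * (1.0 - theta / 90.0)
        )
        if out.ndim == 0:
            return float(out)
        return out


@dataclass(frozen=True)
class TissueClass:
    """One tissue class: fibre geometry, diffusivities and T1 law.

    ``fibre_axes`` are unit 3-vectors (1-3 of them); for ``fan=True``
    classes the first axis must be +z and all axes are rotated per
    mini-bundle so the first axis sweeps the fan angles.
    ``volume_fractions`` are (f1, f2, f3) with f1 >= f2 >= f3 >= 0 and
    f1 + f2 + f3 + f_iso = 1.
    """

    name: str
    fibre_axes: tuple = ((0.0, 0.0, 1.0),)
    volume_fractions: tuple = (1.0, 0.0, 0.0)
    kappa: float = 10.0
    lambda_par: float = 1.7e-3
    lambda_perp: float = 0.3e-3
    d_iso: float = 3.0e-3
    t1_law: AngularT1Law = field(default_factory=lambda: AngularT1Law(800.0))
    s0_base: float = 1000.0
    fan: bool = False
    in_wm: bool = True
    background: bool = False

    def __post_init__(self):
        if self.background:
            return
        f1, f2, f3 = self.volume_fractions
        if not (f1 >= f2 >= f3 >= 0):
            raise ValueError(f"class {self.name}: need f1 >= f2 >= f3 >= 0")
        if f1 + f2 + f3 > 1 + 1e-9:
            raise ValueError(f"class {self.name}: fibre fractions exceed 1")
        if self.kappa < 0:
            raise ValueError(f"class {self.name}: kappa must be >= 0")
        if not self.lambda_par >= self.lambda_perp > 0:
            raise ValueError(f"class {self.name}: need lambda_par >= lambda_perp > 0")
        n_axes = len(self.fibre_axes)
        if not 1 <= n_axes <= 3:
            raise ValueError(f"class {self.name}: 1-3 fibre axes required")
        for ax in self.fibre_axes:
            if abs(np.linalg.norm(ax) - 1.0) > 1e-6:
                raise ValueError(f"class {self.name}: fibre axes must be unit vectors")
        if self.fan and not np.allclose(self.fibre_axes[0], (0.0, 0.0, 1.0)):
            raise ValueError(f"class {self.name}: fan classes need +z as first axis")

    @property
    def f_iso(self) -> float:
        return 1.0 - float(np.sum(self.volume_fractions))

    def active_fractions(self):
        f = np.asarray(self.volume_fractions, dtype=float)
        n = len(self.fibre_axes)
        return f[:n]

    def effective_odi(self) -> float:
        """Single-Watson-equivalent ODI of the class's fibre configuration.

        For a single fibre this is exactly ``odi_from_kappa(kappa)``.  For
        crossing configurations the fraction-weighted mean dyadic is
        collapsed onto its principal axis, which inflates the apparent
        dispersion — mimicking how a one-Watson model reads crossings.
        """
        if self.background:
            return float("nan")
        f = self.active_fractions()
        if f.sum() <= 0:
            return 1.0
        t_mix = np.zeros((3, 3))
        for fi, ax in zip(f, self.fibre_axes):
            t_mix += fi * scatter_matrix(np.asarray(ax, dtype=float), self.kappa)
        t_mix /= f.sum()
        t_eff = float(np.linalg.eigvalsh(t_mix)[-1])
        return odi_from_kappa(kappa_from_cos2(t_eff))


@dataclass
class ScenarioConfig:
    """Full ground-truth description of one synthetic study."""

    field_strength: float
    classes: list
    bvals: tuple
    tis: tuple
    grid_shape: tuple = (40, 40, 20)
    n_dirs_per_shell: int = 64
    n_b0: int = 6
    snr_b0: float = 40.0
    snr_ir: float = 40.0
    s0_reference: float = 1000.0
    n_subjects: int = 11
    seed: int = 1
    eta: float = 1.0
    subject_t1_sd: float = 10.0
    subject_amp_cv: float = 0.12
    s0_slope: float = 0.0
    voxel_size: float = 1.5
    name: str = "scenario"

    def __post_init__(self):
        nx, ny, nz = self.grid_shape
        if nx % N_FAN != 0:
            raise ValueError(f"grid x-dimension must be a multiple of {N_FAN}")
        if nz < 6:
            raise ValueError("grid z-dimension must be >= 6")
        if any(b < 0 for b in self.bvals):
            raise ValueError("b-values must be >= 0")
        if any(ti <= 0 for ti in self.tis):
            raise ValueError("inversion times must be > 0")
        if self.field_strength not in (3.0, 7.0):
            raise ValueError("field_strength must be 3 or 7 (tesla)")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size] * 3 + [1.0])
        return a

    def subjects(self):
        return list(range(1, self.n_subjects + 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("field_strength", "classes", "bvals", "tis"):
            if key not in d:
                raise ValueError(f"scenario config missing required field {key!r}")
        classes = []
        for c in d.pop("classes"):
            c = dict(c)
            law = c.pop("t1_law")
            c["t1_law"] = AngularT1Law(**law)
            c["fibre_axes"] = tuple(tuple(ax) for ax in c["fibre_axes"])
            c["volume_fractions"] = tuple(c["volume_fractions"])
            classes.append(TissueClass(**c))
        for key in ("bvals", "tis", "grid_shape"):
            d[key] = tuple(d[key])
        return cls(classes=classes, **d)


@dataclass
class PhantomLayout:
    """Voxel-wise class labels and fan-group indices.

    ``labels`` holds the index into ``scenario.classes`` (int);
    ``group`` the fan mini-bundle index (0-19) or -1 for non-fan voxels.
    """

    labels: np.ndarray
    group: np.ndarray
    slabs: list


def _allocate_slabs(scenario: ScenarioConfig) -> list:
    """z-slab counts per class: equal counts for all fan classes, the
    remainder split across the others (each >= 1) by largest remainder."""
    nz = scenario.grid_shape[2]
    classes = scenario.classes
    fan_idx = [i for i, c in enumerate(classes) if c.fan]
    other_idx = [i for i, c in enumerate(classes) if not c.fan]
    if not fan_idx:
        raise ValueError("scenario needs at least one fan class")
    n_fan = len(fan_idx)
    k = max(1, int(round(nz * 0.25)))
    while n_fan * k + len(other_idx) > nz and k > 1:
        k -= 1
    rem = nz - n_fan * k
    if rem < len(other_idx):
        raise ValueError("grid z-dimension too small for the class list")
    counts = {i: k for i in fan_idx}
    if other_idx:
        weights = np.array([2.0 if not classes[i].background else 1.0 for i in other_idx])
        share = rem * weights / weights.sum()
        base = np.maximum(np.floor(share).astype(int), 1)
        while base.sum() > rem:
            base[int(np.argmax(base))] -= 1
        leftovers = rem - base.sum()
        order = np.argsort(-(share - base))
        for j in range(leftovers):
            base[order[j % len(base)]] += 1
        for i, c in zip(other_idx, base):
            counts[i] = int(c)
    z0 = 0
    slabs = []
    for i in range(len(classes)):
        slabs.append((z0, z0 + counts[i]))
        z0 += counts[i]
    assert z0 == nz
    return slabs


def build_layout(scenario: ScenarioConfig) -> PhantomLayout:
    nx, ny, nz = scenario.grid_shape
    labels = np.zeros((nx, ny, nz), dtype=int)
    group = np.full((nx, ny, nz), -1, dtype=int)
    slabs = _allocate_slabs(scenario)
    per_group = nx // N_FAN
    x_group = (np.arange(nx) // per_group)[:, None, None]
    for ci, (z0, z1) in enumerate(slabs):
        labels[:, :, z0:z1] = ci
        if scenario.classes[ci].fan:
            group[:, :, z0:z1] = x_group
    return PhantomLayout(labels=labels, group=group, slabs=slabs)


def _rotation_about_y(theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _bundle_axes(tissue: TissueClass, theta_deg: float | None):
    """Fibre axes of one mini-bundle; fan classes rotate all axes about y
    so the first axis makes ``theta_deg`` with +z."""
    axes = [np.asarray(a, dtype=float) for a in tissue.fibre_axes]
    if theta_deg is None:
        return axes
    R = _rotation_about_y(theta_deg)
    return [R @ a for a in axes]


def subject_laws(scenario: ScenarioConfig, subject: int) -> list:
    """Per-subject realisation of each class's T1 law.

    Biological between-subject variability: the baseline gets an additive
    normal shift (sd ``subject_t1_sd``) and the peak/gradient amplitudes a
    multiplicative factor (cv ``subject_amp_cv``), all zero-mean effects.
    """
    rng = np.random.default_rng([scenario.seed, subject, _STREAM_LAW])
    laws = []
    for tissue in scenario.classes:
        shift = rng.normal(0.0, scenario.subject_t1_sd)
        amp_f = max(rng.normal(1.0, scenario.subject_amp_cv), 0.0)
        grad_f = max(rng.normal(1.0, scenario.subject_amp_cv), 0.0)
        law = tissue.t1_law
        laws.append(
            AngularT1Law(
                t1_base=law.t1_base + shift,
                peak_amp=law.peak_amp * amp_f,
                theta_peak=law.theta_peak,
                sigma_peak=law.sigma_peak,
                grad_amp=law.grad_amp * grad_f,
            )
        )
    return laws


def build_truth(scenario: ScenarioConfig, subject: int) -> dict:
    """Ground-truth maps for one subject (includes the subject's T1 law)."""
    layout = build_layout(scenario)
    nx, ny, nz = scenario.grid_shape
    theta = np.full((nx, ny, nz), np.nan)
    t1 = np.full((nx, ny, nz), np.nan)
    s0 = np.zeros((nx, ny, nz))
    odi = np.full((nx, ny, nz), np.nan)
    f_maps = [np.zeros((nx, ny, nz)) for _ in range(3)]
    laws = subject_laws(scenario, subject)
    angles = fan_angles()
    for ci, tissue in enumerate(scenario.classes):
        in_class = layout.labels == ci
        if tissue.background:
            continue
        odi[in_class] = tissue.effective_odi()
        for k, fm in enumerate(f_maps):
            fm[in_class] = tissue.volume_fractions[k]
        if tissue.fan:
            for g, ang in enumerate(angles):
                vox = in_class & (layout.group == g)
                theta[vox] = ang
        else:
            theta[in_class] = fibre_to_field_angle(np.asarray(tissue.fibre_axes[0]))
        t1[in_class] = laws[ci](theta[in_class])
        th_for_s0 = np.nan_to_num(theta[in_class], nan=0.0)
        s0[in_class] = tissue.s0_base * (1.0 + scenario.s0_slope * th_for_s0 / 90.0)
    tissue_mask = ~np.array(
        [c.background for c in scenario.classes], dtype=bool
    )[layout.labels]
    wm_mask = np.array([c.in_wm for c in scenario.classes], dtype=bool)[layout.labels]
    return {
        "labels": layout.labels,
        "group": layout.group,
        "theta": theta,
        "t1": t1,
        "s0": s0,
        "odi": odi,
        "f1": f_maps[0],
        "f2": f_maps[1],
        "f3": f_maps[2],
        "tissue_mask": tissue_mask,
        "wm_mask": wm_mask,
    }


def fibonacci_hemisphere(n: int, offset: float = 0.0) -> np.ndarray:
    """Deterministic near-uniform directions on the upper hemisphere (3, n)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    z = i / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i + offset
    s = np.sqrt(1.0 - z * z)
    return np.vstack([s * np.cos(phi), s * np.sin(phi), z])


def gradient_table(scenario: ScenarioConfig):
    """(bvals, bvecs) for the scenario: b0 block then one block per shell."""
    bvals = [0.0] * scenario.n_b0
    bvecs = [np.zeros((3, scenario.n_b0))]
    for si, b in enumerate(scenario.bvals):
        bvals += [float(b)] * scenario.n_dirs_per_shell
        bvecs.append(fibonacci_hemisphere(scenario.n_dirs_per_shell, offset=0.61 * si))
    return np.asarray(bvals), np.concatenate(bvecs, axis=1)


def rician(signal, sigma: float, rng) -> np.ndarray:
    """Magnitude of the signal with complex Gaussian noise of sd ``sigma``."""
    signal = np.asarray(signal, dtype=float)
    if sigma == 0 or not np.isfinite(1.0 / max(sigma, 1e-300)):
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re * re + im * im)


def _class_signal(tissue: TissueClass, theta_deg, bvals, bvecs) -> np.ndarray:
    """Noise-free DWI signal (one value per volume) for one mini-bundle."""
    axes = _bundle_axes(tissue, theta_deg)
    t = cos2_moment(tissue.kappa)
    fractions = tissue.active_fractions()
    sig = np.zeros(bvals.size)
    for fi, ax in zip(fractions, axes):
        outer = np.outer(ax, ax)
        scat = t * outer + 0.5 * (1.0 - t) * (np.eye(3) - outer)
        D = tissue.lambda_perp * np.eye(3) + (tissue.lambda_par - tissue.lambda_perp) * scat
        quad_form = np.einsum("in,ij,jn->n", bvecs, D, bvecs)
        sig += fi * np.exp(-bvals * quad_form)
    if tissue.f_iso > 0:
        sig += tissue.f_iso * np.exp(-bvals * tissue.d_iso)
    return tissue.s0_base * sig


def simulate_dwi(scenario: ScenarioConfig, subject: int) -> DWIDataset:
    """Simulate one subject's diffusion acquisition (with Rician noise)."""
    if subject not in scenario.subjects():
        raise ValueError(f"subject {subject} not in 1..{scenario.n_subjects}")
    layout = build_layout(scenario)
    bvals, bvecs = gradient_table(scenario)
    nx, ny, nz = scenario.grid_shape
    data = np.zeros((nx, ny, nz, bvals.size))
    angles = fan_angles()
    for ci, tissue in enumerate(scenario.classes):
        if tissue.background:
            continue
        in_class = layout.labels == ci
        if tissue.fan:
            for g, ang in enumerate(angles):
                vox = in_class & (layout.group == g)
                data[vox] = _class_signal(tissue, float(ang), bvals, bvecs)
        else:
            data[in_class] = _class_signal(tissue, None, bvals, bvecs)
    if np.isfinite(scenario.snr_b0):
        sigma = scenario.s0_reference / scenario.snr_b0
        rng = np.random.default_rng([scenario.seed, subject, _STREAM_DWI])
        data = rician(data, sigma, rng)
    mask = ~np.array([c.background for c in scenario.classes], dtype=bool)[layout.labels]
    return DWIDataset(data=data, bvals=bvals, bvecs=bvecs, mask=mask, affine=scenario.affine)


def simulate_ir(scenario: ScenarioConfig, subject: int, truth: dict | None = None) -> np.ndarray:
    """Simulate the multi-TI inversion-recovery magnitude series (4D)."""
    if truth is None:
        truth = build_truth(scenario, subject)
    tis = np.asarray(scenario.tis, dtype=float)
    if np.any(tis <= 0):
        raise ValueError("inversion times must be > 0")
    t1 = truth["t1"]
    s0 = truth["s0"]
    with np.errstate(invalid="ignore", divide="ignore"):
        decay = np.exp(-tis[None, None, None, :] / t1[..., None])
    signal = np.abs(s0[..., None] * (1.0 - 2.0 * scenario.eta * decay))
    signal = np.nan_to_num(signal, nan=0.0)
    if np.isfinite(scenario.snr_ir):
        sigma = scenario.s0_reference / scenario.snr_ir
        rng = np.random.default_rng([scenario.seed, subject, _STREAM_IR])
        signal = rician(signal, sigma, rng)
    return signal


def export_ground_truth(scenario: ScenarioConfig, subject: int, out_dir) -> dict:
    """Write per-subject truth maps as NIfTI; returns path -> array map."""
    from pathlib import Path

    from .io import save_nifti

    truth = build_truth(scenario, subject)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for key in ("theta", "t1", "s0", "odi", "f1", "f2", "f3"):
        path = out_dir / f"true_{key}.nii.gz"
        save_nifti(path, truth[key], scenario.affine)
        written[str(path)] = truth[key]
    for key in ("labels", "tissue_mask", "wm_mask"):
        path = out_dir / f"{key}.nii.gz"
        save_nifti(path, truth[key].astype(np.int16), scenario.affine)
        written[str(path)] = truth[key]
    return written
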