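"""Synthetic brain phantoms: template, cohorts and clinical covariates.

Real presymptomatic-carrier imaging cohorts are not redistributable, so every
downstream stage of this package is exercised on phantoms generated here.
The generator emulates the statistical structure the analysis assumes:

* tracer uptake linear in age per voxel, scaled by grey-matter probability,
  with gaussian voxel noise added after an acquisition blur;
* carrier-specific regional lesions — multiplicative hypometabolism of order
  15-35% in deep and fronto-insular grey matter, focal hypermetabolism of
  order 5-10% in the peri-Rolandic region;
* regional grey-matter atrophy of order 20% on the modulated GM-volume maps;
* skewed CSF neurofilament markers, with an elevated mixture component so a
  minority of carriers surpass the NfL diagnostic cutoff (1227 pg/mL);
* ECAS cognitive subdomain scores, abnormal (below the 5th normative
  percentile) in a minority of carriers;
* upper-motor-neuron signs in a majority of carriers.

Phantoms are born directly in a shared isotropic analysis space; spatial
normalisation is out of scope by construction.  The atlas is a deterministic
arrangement of ellipsoidal parcels whose names mirror the anatomical roles
the analysis needs (occipital exclusion, cerebellar reference, deep nuclei
lesion targets); it makes no attempt at realistic cortical folding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Volume, gaussian_blur

# ---------------------------------------------------------------------------
# Generative parameters


def _default_lesions() -> list[tuple[str, float]]:
    # signed metabolic effect fractions; chosen inside the ranges the method
    # is expected to resolve (deep/insular hypometabolism, focal
    # peri-Rolandic hypermetabolism)
    return [
        ("thalamus", -0.25),
        ("basal_ganglia", -0.30),
        ("insula", -0.25),
        ("frontal", -0.20),
        ("peri_rolandic", +0.06),
    ]


def _default_atrophy() -> list[tuple[str, float]]:
    return [
        ("thalamus", -0.20),
        ("insula", -0.20),
        ("central_operculum", -0.20),
    ]


def _default_nf_params() -> dict:
    return {
        "nfl": {
            "control": {"median": 600.0, "sigma": 0.35},
            "carrier": {"median": 650.0, "sigma": 0.35,
                        "elevated_fraction": 0.19,
                        "elevated_median": 1600.0, "elevated_sigma": 0.15},
        },
        "pnfh": {
            "control": {"median": 190.0, "sigma": 0.30},
            "carrier": {"median": 195.0, "sigma": 0.30},
        },
    }


def _default_ecas_params() -> dict:
    # normative mean/SD per subdomain; carriers score below the 5th
    # percentile on one subdomain with probability abnormal_fraction
    return {
        "norms": {
            "language": {"mean": 26.0, "sd": 2.0},
            "fluency": {"mean": 20.0, "sd": 2.5},
            "executive": {"mean": 38.0, "sd": 4.0},
            "memory": {"mean": 16.0, "sd": 3.0},
            "visuospatial": {"mean": 11.0, "sd": 1.0},
        },
        "abnormal_fraction": 0.29,
        "abnormal_shift_sd": -2.5,
    }


@dataclass
class PhantomSpec:
    """Generative assumptions for one phantom world.

    Defaults mirror the study conditions the pipeline is meant to analyse:
    17 carriers vs 25 controls, ages spanning early presymptomatic decades,
    uptake declining linearly with age, 5.5 mm acquisition blur, and the
    lesion/atrophy fractions listed above.
    """

    grid_dims: tuple[int, int, int] = (48, 56, 48)
    voxel_mm: float = 3.0
    n_controls: int = 25
    n_carriers: int = 17
    age_range: tuple[float, float] = (30.0, 65.0)
    baseline_intercept: float = 100.0       # uptake a.u. at age 0
    age_slope: float = -0.5                 # a.u. per year
    noise_sd: float = 2.0                   # post-blur gaussian voxel noise
    acquisition_fwhm_mm: float = 5.5
    gm_blur_fwhm_mm: float = 2.0            # segmentation smoothness of GM maps
    gm_noise_sd: float = 0.01
    tiv_cv: float = 0.05
    lesion_defs: list = field(default_factory=_default_lesions)
    atrophy_defs: list = field(default_factory=_default_atrophy)
    nf_params: dict = field(default_factory=_default_nf_params)
    ecas_params: dict = field(default_factory=_default_ecas_params)
    sex_female_prob: dict = field(
        default_factory=lambda: {"control": 0.48, "carrier": 0.71})
    umn_prob: dict = field(default_factory=lambda: {"control": 0.0, "carrier": 0.59})
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.age_range = tuple(float(a) for a in self.age_range)
        self.lesion_defs = [(str(n), float(f)) for n, f in self.lesion_defs]
        self.atrophy_defs = [(str(n), float(f)) for n, f in self.atrophy_defs]
        if len(self.grid_dims) != 3 or any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must be 3 axes of >= 8 voxels each")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.n_controls < 3:
            raise ValueError("n_controls must be >= 3")
        if self.n_carriers < 0:
            raise ValueError("n_carriers must be >= 0")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age_range must be nondegenerate (lo < hi)")
        for name, frac in list(self.lesion_defs) + list(self.atrophy_defs):
            if not -1.0 < frac < 1.0:
                raise ValueError(
                    f"effect fraction for {name!r} must be in (-1, 1), got {frac}")
        if self.noise_sd < 0 or self.gm_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.acquisition_fwhm_mm < 0:
            raise ValueError("acquisition_fwhm_mm must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(d["grid_dims"])
        d["age_range"] = list(d["age_range"])
        d["lesion_defs"] = [list(t) for t in d["lesion_defs"]]
        d["atrophy_defs"] = [list(t) for t in d["atrophy_defs"]]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["grid_dims"] = tuple(d["grid_dims"])
        d["age_range"] = tuple(d["age_range"])
        d["lesion_defs"] = [tuple(t) for t in d["lesion_defs"]]
        d["atrophy_defs"] = [tuple(t) for t in d["atrophy_defs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Template


@dataclass
class Atlas:
    """Integer label image plus the name of each label."""

    volume: Volume
    names: dict[str, int]

    def mask(self, *names: str) -> np.ndarray:
        """Boolean array over the listed region names."""
        out = np.zeros(self.volume.shape, dtype=bool)
        for name in names:
            if name not in self.names:
                raise KeyError(f"atlas has no region named {name!r}; "
                               f"known: {sorted(self.names)}")
            out |= self.volume.data == self.names[name]
        return out

    @property
    def labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.volume.data) if v > 0)


@dataclass
class TemplateSet:
    """GM/WM/CSF probability maps plus atlas for one phantom world."""

    gm_prob: Volume
    wm_prob: Volume
    csf_prob: Volume
    atlas: Atlas
    tiv_reference: float  # mm^3


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def build_template(spec: PhantomSpec) -> TemplateSet:
    """Deterministic template: tissue priors, named atlas, TIV reference.

    The cerebrum is an ellipsoid with a WM core and a GM shell; deep grey
    nuclei (thalamus, basal ganglia) and insular blobs are carved out of the
    core as GM.  A separate inferior-posterior ellipsoid is the cerebellum.
    Parcel centres are jittered by at most one voxel from the seed so
    different worlds differ while geometric invariants hold.
    """
    nx, ny, nz = spec.grid_dims
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA71A5]))
    jit = lambda: rng.integers(-1, 2, size=3)  # noqa: E731

    shape = (nx, ny, nz)
    # axes: x left-right, y anterior(0)-posterior(ny), z inferior(0)-superior(nz)
    c_cer = np.array([nx / 2, ny * 0.46, nz * 0.58])
    a_cer = np.array([nx * 0.40, ny * 0.40, nz * 0.36])
    grids = np.ogrid[0:nx, 0:ny, 0:nz]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, c_cer, a_cer))
    r = np.sqrt(r2)
    cerebrum = r <= 1.0
    wm_core = r <= 0.68
    # normalised coordinates within the cerebrum ellipsoid
    u = (grids[0] - c_cer[0]) / a_cer[0] + np.zeros(shape)
    v = (grids[1] - c_cer[1]) / a_cer[1] + np.zeros(shape)
    w = (grids[2] - c_cer[2]) / a_cer[2] + np.zeros(shape)

    # cerebellum: inferior-posterior ellipsoid, outside the cerebrum
    c_cb = np.array([nx / 2, ny * 0.72, nz * 0.20]) + jit()
    a_cb = np.array([nx * 0.22, ny * 0.16, nz * 0.13])
    cerebellum = _ellipsoid(shape, c_cb, a_cb) & ~cerebrum

    # deep grey carved from the WM core
    vox_of = lambda fu, fv, fw: c_cer + np.array([fu, fv, fw]) * a_cer  # noqa: E731
    thal = np.zeros(shape, dtype=bool)
    bg = np.zeros(shape, dtype=bool)
    ins = np.zeros(shape, dtype=bool)
    for s in (-1, 1):
        thal |= _ellipsoid(shape, vox_of(0.20 * s, 0.06, -0.04) + jit(),
                           (nx * 0.085, ny * 0.10, nz * 0.085))
        bg |= _ellipsoid(shape, vox_of(0.42 * s, -0.12, 0.02) + jit(),
                         (nx * 0.075, ny * 0.11, nz * 0.075))
        ins |= _ellipsoid(shape, vox_of(0.62 * s, -0.02, -0.02) + jit(),
                          (nx * 0.07, ny * 0.12, nz * 0.10))
    deep_gm = (thal | bg | ins) & cerebrum

    gm_shell = cerebrum & ~wm_core
    gm_ind = (gm_shell | deep_gm) & ~cerebellum
    wm_ind = wm_core & ~deep_gm
    cb_wm = _ellipsoid(shape, c_cb, a_cb * 0.45) & cerebellum
    brain = cerebrum | cerebellum
    csf_ind = _ellipsoid(shape, c_cer, a_cer * 1.10) & ~brain

    gm_full = gm_ind | (cerebellum & ~cb_wm)
    wm_full = wm_ind | cb_wm

    blur = lambda ind: gaussian_blur(  # noqa: E731
        Volume(ind.astype(float), spec.voxel_mm), 1.2 * spec.voxel_mm).data
    gm_prob = blur(gm_full)
    wm_prob = blur(wm_full)
    csf_prob = blur(csf_ind)

    # ------------------------------------------------------------------ atlas
    names = {
        "frontal": 1, "temporal": 2, "parietal": 3, "occipital": 4,
        "peri_rolandic": 5, "central_operculum": 6, "precuneus": 7,
        "insula": 8, "thalamus": 9, "basal_ganglia": 10,
        "other_cortex": 11, "cerebellum": 12,
    }
    atlas = np.zeros(shape, dtype=np.int16)
    shell = gm_shell & ~deep_gm & ~cerebellum
    atlas[shell] = names["other_cortex"]

    def put(mask, name):
        atlas[mask] = names[name]

    put(shell & (v < -0.35), "frontal")
    put(shell & (v >= -0.35) & (v <= 0.45) & (w < -0.30), "temporal")
    put(shell & (v > -0.05) & (v <= 0.45) & (w >= -0.30), "parietal")
    put(shell & (v >= -0.05) & (v <= 0.45) & (np.abs(u) < 0.42) & (w > 0.40),
        "precuneus")
    put(shell & (v >= -0.35) & (v <= -0.05) & (w > 0.30), "peri_rolandic")
    put(shell & (np.abs(v) <= 0.22) & (np.abs(u) > 0.55)
        & (w > -0.12) & (w <= 0.30), "central_operculum")
    put(shell & (v > 0.45), "occipital")
    put(ins & cerebrum, "insula")
    put(bg & cerebrum, "basal_ganglia")
    put(thal & cerebrum, "thalamus")
    put(cerebellum, "cerebellum")
    # only keep labels where tissue actually is
    atlas[~(gm_full | wm_full)] = 0

    tiv_reference = float((brain | csf_ind).sum()) * spec.voxel_mm ** 3

    mk = lambda a: Volume(a, spec.voxel_mm)  # noqa: E731
    return TemplateSet(
        gm_prob=mk(gm_prob), wm_prob=mk(wm_prob), csf_prob=mk(csf_prob),
        atlas=Atlas(mk(atlas.astype(np.int16)), names),
        tiv_reference=tiv_reference,
    )


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SubjectRecord:
    """One participant: group, demographics, images, fluid and clinical data."""

    subject_id: str
    group: str              # "control" | "carrier"
    sex: str                # "F" | "M"
    age: float              # years
    tiv: float              # mm^3
    uptake: Volume
    gm_volume: Volume
    nfl: float              # pg/mL
    pnfh: float             # pg/mL
    ecas: dict[str, float]
    umn_sign: bool


def _lognormal(rng, median: float, sigma: float) -> float:
    return float(np.exp(np.log(median) + sigma * rng.standard_normal()))


def _draw_nf(rng, params: dict) -> float:
    frac = params.get("elevated_fraction", 0.0)
    if frac and rng.random() < frac:
        return _lognormal(rng, params["elevated_median"],
                          params["elevated_sigma"])
    return _lognormal(rng, params["median"], params["sigma"])


def noise_free_uptake(spec: PhantomSpec, template: TemplateSet, age: float,
                      group: str = "control", blur: bool = True) -> Volume:
    """Expected uptake image for a subject of the given age and group.

    intercept + slope*age per voxel, scaled by GM probability, with the
    carrier lesions applied multiplicatively, then the acquisition blur.
    """
    base = (spec.baseline_intercept + spec.age_slope * age) \
        * template.gm_prob.data
    if group == "carrier":
        for region, frac in spec.lesion_defs:
            base = np.where(template.atlas.mask(region), base * (1.0 + frac),
                            base)
    vol = Volume(base, spec.voxel_mm)
    if blur and spec.acquisition_fwhm_mm > 0:
        vol = gaussian_blur(vol, spec.acquisition_fwhm_mm)
    return vol


def noise_free_gm_volume(spec: PhantomSpec, template: TemplateSet, tiv: float,
                         group: str = "control", blur: bool = True) -> Volume:
    """Expected modulated GM-volume image: GM probability scaled by relative
    head size, with carrier atrophy applied multiplicatively."""
    base = template.gm_prob.data * (tiv / template.tiv_reference)
    if group == "carrier":
        for region, frac in spec.atrophy_defs:
            base = np.where(template.atlas.mask(region), base * (1.0 + frac),
                            base)
    vol = Volume(base, spec.voxel_mm)
    if blur and spec.gm_blur_fwhm_mm > 0:
        vol = gaussian_blur(vol, spec.gm_blur_fwhm_mm)
    return vol


def simulate_cohort(spec: PhantomSpec,
                    template: TemplateSet) -> list[SubjectRecord]:
    """Simulate controls then carriers; deterministic for a given seed."""
    if spec.n_controls + spec.n_carriers == 0:
        raise ValueError("cohort must contain at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0407]))
    lo, hi = spec.age_range
    records: list[SubjectRecord] = []
    groups = ["control"] * spec.n_controls + ["carrier"] * spec.n_carriers
    for i, group in enumerate(groups):
        age = float(rng.uniform(lo, hi))
        sex = "F" if rng.random() < spec.sex_female_prob[group] else "M"
        tiv = float(template.tiv_reference
                    * (1.0 + spec.tiv_cv * rng.standard_normal()))

        uptake = noise_free_uptake(spec, template, age, group)
        up = uptake.data + spec.noise_sd * rng.standard_normal(uptake.shape)
        gmv = noise_free_gm_volume(spec, template, tiv, group)
        gv = gmv.data + spec.gm_noise_sd * rng.standard_normal(gmv.shape)

        nfl = _draw_nf(rng, spec.nf_params["nfl"][group])
        pnfh = _draw_nf(rng, spec.nf_params["pnfh"][group])

        norms = spec.ecas_params["norms"]
        ecas = {k: float(p["mean"] + p["sd"] * rng.standard_normal())
                for k, p in norms.items()}
        if group == "carrier" and \
                rng.random() < spec.ecas_params["abnormal_fraction"]:
            dom = list(norms)[rng.integers(len(norms))]
            ecas[dom] = float(norms[dom]["mean"]
                              + spec.ecas_params["abnormal_shift_sd"]
                              * norms[dom]["sd"])
        umn = bool(rng.random() < spec.umn_prob[group])

        records.append(SubjectRecord(
            subject_id=f"sub-{i + 1:03d}", group=group, sex=sex, age=age,
            tiv=tiv, uptake=Volume(up, spec.voxel_mm),
            gm_volume=Volume(gv, spec.voxel_mm),
            nfl=nfl, pnfh=pnfh, ecas=ecas, umn_sign=umn))
    return records


# ---------------------------------------------------------------------------
# I/O


def participants_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "sex": r.sex,
               "age": r.age, "tiv": r.tiv, "nfl": r.nfl, "pnfh": r.pnfh,
               "umn_sign": r.umn_sign}
        row.update({f"ecas_{k}": v for k, v in r.ecas.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecord], template: TemplateSet,
                 spec: PhantomSpec, outdir) -> None:
    """NIfTI volumes per subject/modality, participants TSV, spec sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template.gm_prob.save(outdir / "template_gm_prob.nii")
    template.wm_prob.save(outdir / "template_wm_prob.nii")
    template.csf_prob.save(outdir / "template_csf_prob.nii")
    template.atlas.volume.save(outdir / "template_atlas.nii")
    (outdir / "template_atlas_labels.json").write_text(
        json.dumps(template.atlas.names, indent=1, sort_keys=True))
    for r in records:
        r.uptake.save(outdir / f"{r.subject_id}_pet.nii")
        r.gm_volume.save(outdir / f"{r.subject_id}_gmvol.nii")
    participants_frame(records).to_csv(outdir / "participants.tsv", sep="\t",
                                       index=False)
    (outdir / "phantom_spec.json").write_text(spec.to_json())
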