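"""End-to-end orchestration: simulate -> PVC -> preprocess -> GLM ->
W-score -> VOI -> clinical -> report.

Each stage reads its inputs from the run directory and writes its outputs
there, so any single stage can be re-run from cached inputs and reproduce
its outputs exactly.  All thresholds live in :class:`RunConfig` with the
analysis defaults (height p < .001, cluster-level FWE p < .05, extent 150
voxels, |W| >= 1.96, GM mask threshold 0.1, PSF 5.5 mm, smoothing 8 mm,
NfL/pNfH cutoffs 1227/750 pg/mL); seeds are explicit and echoed in the
provenance report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import glm, phantom, pvc, regional, wscore
from . import preprocess as prep
from .volume import Volume

STAGES = ("simulate", "pvc", "preprocess", "glm", "wscore", "voi",
          "clinical", "report")

#: thresholds that must be present in a config file
REQUIRED_KEYS = (
    "height_p", "cluster_p", "extent", "w_threshold", "mask_threshold",
    "pvc_fwhm_mm", "smooth_fwhm_mm", "wm_threshold", "gm_threshold",
    "nfl_cutoff", "pnfh_cutoff", "ecas_percentile", "n_perm", "seed",
)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """All analysis thresholds and seeds for one pipeline run."""

    phantom: phantom.PhantomSpec = field(default_factory=phantom.PhantomSpec)
    height_p: float = 0.001
    cluster_p: float = 0.05
    extent: int = 150
    w_threshold: float = 1.96
    mask_threshold: float = 0.1
    pvc_fwhm_mm: float = 5.5
    smooth_fwhm_mm: float = 8.0
    wm_threshold: float = 0.95
    gm_threshold: float = 0.3
    nfl_cutoff: float = 1227.0
    pnfh_cutoff: float = 750.0
    ecas_percentile: float = 5.0
    connectivity: int = 18
    n_perm: int = 1000
    seed: int = 0
    excluded_labels: tuple = ("occipital",)
    reference_labels: tuple = ("cerebellum",)

    def validate(self) -> None:
        if not 0 < self.height_p <= 0.5:
            raise ConfigError("height_p must be in (0, 0.5]")
        if not 0 < self.cluster_p < 1:
            raise ConfigError("cluster_p must be in (0, 1)")
        if self.extent < 1:
            raise ConfigError("extent must be >= 1")
        if self.w_threshold <= 0:
            raise ConfigError("w_threshold must be positive")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        missing = [k for k in REQUIRED_KEYS if k not in raw]
        if missing:
            raise ConfigError(
                f"config is missing required keys: {', '.join(missing)}")
        spec = phantom.PhantomSpec(**raw.pop("phantom", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"phantom"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(phantom=spec, **{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["phantom"] = json.loads(self.phantom.to_json())
        d["excluded_labels"] = list(self.excluded_labels)
        d["reference_labels"] = list(self.reference_labels)
        return yaml.safe_dump(d, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and subject context."""

    def __init__(self, stage: str, message: str, subject: str | None = None):
        where = f"stage {stage!r}" + (f", subject {subject}" if subject else "")
        super().__init__(f"{where}: {message}")
        self.stage = stage
        self.subject = subject


# ---------------------------------------------------------------------------
# Cached-input helpers


def _load_template(rundir: Path, vox: float) -> phantom.TemplateSet:
    sim = rundir / "simulate"
    names = json.loads((sim / "template_atlas_labels.json").read_text())
    atlas_vol = Volume.load(sim / "template_atlas.nii")
    atlas_vol.data = np.round(atlas_vol.data).astype(np.int16)
    return phantom.TemplateSet(
        gm_prob=Volume.load(sim / "template_gm_prob.nii"),
        wm_prob=Volume.load(sim / "template_wm_prob.nii"),
        csf_prob=Volume.load(sim / "template_csf_prob.nii"),
        atlas=phantom.Atlas(atlas_vol, {k: int(v) for k, v in names.items()}),
        tiv_reference=0.0,
    )


def _participants(rundir: Path) -> pd.DataFrame:
    return pd.read_csv(rundir / "simulate" / "participants.tsv", sep="\t")


def _subject_vols(rundir: Path, stage: str, suffix: str,
                  ids) -> list[Volume]:
    return [Volume.load(rundir / stage / f"{sid}_{suffix}.nii")
            for sid in ids]


def _save_table(tab: pd.DataFrame, path: Path) -> None:
    tab.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    template = phantom.build_template(cfg.phantom)
    records = phantom.simulate_cohort(cfg.phantom, template)
    phantom.write_cohort(records, template, cfg.phantom, rundir / "simulate")


def stage_pvc(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "pvc"
    out.mkdir(parents=True, exist_ok=True)
    template = _load_template(rundir, cfg.phantom.voxel_mm)
    part = _participants(rundir)
    psf = pvc.PSFModel(cfg.pvc_fwhm_mm)
    rows = []
    for sid in part["subject_id"]:
        try:
            pet = Volume.load(rundir / "simulate" / f"{sid}_pet.nii")
            wm_act = pvc.estimate_wm_activity(pet, template.wm_prob, psf,
                                              cfg.wm_threshold)
            corr = pvc.muller_gartner(pet, template.gm_prob, template.wm_prob,
                                      wm_act, psf, cfg.gm_threshold)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise StageError("pvc", str(exc), subject=sid) from exc
        corr.save(out / f"{sid}_pet_pvc.nii")
        rep = pvc.pvc_report(corr)
        rep.insert(0, "subject_id", sid)
        rows.append(rep)
    _save_table(pd.concat(rows, ignore_index=True), out / "pvc_report.tsv")


def stage_preprocess(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    template = _load_template(rundir, cfg.phantom.voxel_mm)
    part = _participants(rundir)
    ids = list(part["subject_id"])

    gmvols = _subject_vols(rundir, "simulate", "gmvol", ids)
    mean_gm = gmvols[0].like(np.mean([v.data for v in gmvols], axis=0))
    mask = prep.make_analysis_mask(mean_gm, template.atlas,
                                   cfg.mask_threshold,
                                   set(cfg.excluded_labels))
    mask.mask.like(mask.array.astype(np.uint8)).save(out / "analysis_mask.nii")
    (out / "analysis_mask.json").write_text(
        json.dumps(mask.provenance, indent=1, sort_keys=True))

    for sid, gmv in zip(ids, gmvols):
        pet = Volume.load(rundir / "simulate" / f"{sid}_pet.nii")
        pet_pvc = Volume.load(rundir / "pvc" / f"{sid}_pet_pvc.nii")
        norm_raw = prep.proportional_normalize(pet, mask)
        norm_pvc = prep.proportional_normalize(pet_pvc, mask)
        suvr_raw = prep.suvr(pet, template.atlas, set(cfg.reference_labels))
        prep.smooth(norm_raw, cfg.smooth_fwhm_mm).save(
            out / f"{sid}_pet_norm_smooth.nii")
        prep.smooth(norm_pvc, cfg.smooth_fwhm_mm, mask).save(
            out / f"{sid}_pet_pvc_norm_smooth.nii")
        prep.smooth(suvr_raw, cfg.smooth_fwhm_mm).save(
            out / f"{sid}_pet_suvr_smooth.nii")
        prep.smooth(gmv, cfg.smooth_fwhm_mm).save(
            out / f"{sid}_gmvol_smooth.nii")


def _cluster_analysis(cfg: RunConfig, images, part, mask, direction,
                      tiv=None, seed_offset=0) -> pd.DataFrame:
    design = glm.make_group_design(part["group"], part["age"], tiv,
                                   direction=direction)
    return glm.cluster_fwe(
        images, design, mask, n_perm=cfg.n_perm,
        seed=cfg.seed + seed_offset, height_p=cfg.height_p,
        extent=cfg.extent, cluster_p=cfg.cluster_p,
        connectivity=cfg.connectivity, groups=part["group"])


def stage_glm(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "glm"
    out.mkdir(parents=True, exist_ok=True)
    part = _participants(rundir)
    ids = list(part["subject_id"])
    mask = prep.AnalysisMask(
        Volume.load(rundir / "preprocess" / "analysis_mask.nii"),
        json.loads((rundir / "preprocess" / "analysis_mask.json").read_text()))

    analyses = {
        "fdg_hypo": ("pet_norm_smooth", "hypo", None, 1),
        "fdg_hyper": ("pet_norm_smooth", "hyper", None, 2),
        "fdg_pvc_hypo": ("pet_pvc_norm_smooth", "hypo", None, 3),
        "vbm_hypo": ("gmvol_smooth", "hypo", part["tiv"], 4),
    }
    prov = {"seed": cfg.seed, "n_perm": cfg.n_perm, "height_p": cfg.height_p,
            "cluster_p": cfg.cluster_p, "extent": cfg.extent,
            "connectivity": cfg.connectivity}
    for name, (suffix, direction, tiv, off) in analyses.items():
        images = _subject_vols(rundir, "preprocess", suffix, ids)
        table = _cluster_analysis(cfg, images, part, mask, direction, tiv,
                                  off)
        _save_table(table, out / f"clusters_{name}.tsv")
        design = glm.make_group_design(part["group"], part["age"], tiv,
                                       direction=direction)
        tmap, df = glm.fit_glm(images, design, mask)
        tmap.save(out / f"tmap_{name}.nii")
        prov[f"df_{name}"] = df

    # age-slope interaction on the modality of primary interest
    images = _subject_vols(rundir, "preprocess", "pet_norm_smooth", ids)
    tmap, df = glm.slope_interaction_test(images, part["age"], part["group"],
                                          mask)
    tmap.save(out / "tmap_slope_interaction.nii")
    prov["df_slope_interaction"] = df
    (out / "provenance.json").write_text(json.dumps(prov, indent=1,
                                                    sort_keys=True))


def stage_wscore(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "wscore"
    out.mkdir(parents=True, exist_ok=True)
    template = _load_template(rundir, cfg.phantom.voxel_mm)
    part = _participants(rundir)
    mask = prep.AnalysisMask(
        Volume.load(rundir / "preprocess" / "analysis_mask.nii"),
        json.loads((rundir / "preprocess" / "analysis_mask.json").read_text()))
    ctrl = part[part["group"] == "control"]
    carr = part[part["group"] == "carrier"]
    if len(carr) == 0:
        raise StageError("wscore", "no carriers to map")

    for suffix, direction in (("pet_norm_smooth", "hypo"),
                              ("pet_pvc_norm_smooth", "hyper"),
                              ("gmvol_smooth", "hypo")):
        ctrl_imgs = _subject_vols(rundir, "preprocess", suffix,
                                  ctrl["subject_id"])
        model = wscore.fit_normative(ctrl_imgs, ctrl["age"], mask)
        wmaps = []
        for sid, age in zip(carr["subject_id"], carr["age"]):
            img = Volume.load(rundir / "preprocess" / f"{sid}_{suffix}.nii")
            wm = wscore.wmap(img, float(age), model, subject_id=sid)
            wm.w.save(out / f"{sid}_w_{suffix}.nii")
            wmaps.append(wm)
        binaries = [wscore.binarize_w(w, direction, cfg.w_threshold)
                    for w in wmaps]
        counts, frac, summary = wscore.frequency_map(binaries)
        counts.save(out / f"freq_counts_{suffix}_{direction}.nii")
        frac.save(out / f"freq_fraction_{suffix}_{direction}.nii")
        wscore.mean_wmap(wmaps).save(out / f"mean_w_{suffix}.nii")
        (out / f"freq_summary_{suffix}_{direction}.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        _save_table(
            wscore.region_flag_counts(wmaps, template.atlas, mask, direction,
                                      cfg.w_threshold),
            out / f"region_flags_{suffix}_{direction}.tsv")


def stage_voi(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "voi"
    out.mkdir(parents=True, exist_ok=True)
    template = _load_template(rundir, cfg.phantom.voxel_mm)
    part = _participants(rundir)
    psf = pvc.PSFModel(cfg.pvc_fwhm_mm)
    frames = []
    for sid in part["subject_id"]:
        pet = Volume.load(rundir / "simulate" / f"{sid}_pet.nii")
        try:
            tab = pvc.region_based_correct(pet, template.atlas,
                                           template.gm_prob,
                                           template.wm_prob, psf)
        except Exception as exc:  # noqa: BLE001
            raise StageError("voi", str(exc), subject=sid) from exc
        # normalise corrected means to their grand mean so the regional
        # contrast matches the proportionally scaled voxel analyses
        tab = tab.rename(columns={"corrected_mean": "mean"})
        tab["mean"] /= tab["mean"].mean()
        tab.insert(0, "subject_id", sid)
        frames.append(tab[["subject_id", "region", "size_voxels", "mean"]])
    table = pd.concat(frames, ignore_index=True)
    table = table[~table["region"].isin(set(cfg.excluded_labels)
                                        | {"white_matter"})]
    _save_table(table, out / "region_means.tsv")

    groups = dict(zip(part["subject_id"], part["group"]))
    ages = dict(zip(part["subject_id"], part["age"]))
    for direction in ("hypo", "hyper"):
        stats_tab = regional.group_compare_regions(table, groups, ages,
                                                   direction=direction)
        _save_table(regional.bh_report(stats_tab, cfg.cluster_p),
                    out / f"region_tests_{direction}.tsv")


def stage_clinical(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "clinical"
    out.mkdir(parents=True, exist_ok=True)
    part = _participants(rundir)
    cut = clin.CutoffConfig(cfg.nfl_cutoff, cfg.pnfh_cutoff,
                            cfg.ecas_percentile)
    norms = cfg.phantom.ecas_params["norms"]
    records = []
    for _, row in part.iterrows():
        ecas = {k.removeprefix("ecas_"): row[k]
                for k in part.columns if k.startswith("ecas_")}
        records.append(phantom.SubjectRecord(
            subject_id=row["subject_id"], group=row["group"], sex=row["sex"],
            age=row["age"], tiv=row["tiv"], uptake=None, gm_volume=None,
            nfl=row["nfl"], pnfh=row["pnfh"], ecas=ecas,
            umn_sign=bool(row["umn_sign"])))
    summary = clin.cohort_summary(records, cut, ecas_norms=norms)
    _save_table(summary, out / "cohort_summary.tsv")

    flags = []
    for r in records:
        f = clin.flag_nf(r.nfl, r.pnfh, cut)
        _, n_abn = clin.classify_ecas(r.ecas, norms, cut)
        flags.append({"subject_id": r.subject_id, "group": r.group,
                      **f, "ecas_abnormal_domains": n_abn})
    _save_table(pd.DataFrame(flags), out / "subject_flags.tsv")


def stage_report(cfg: RunConfig, rundir: Path) -> None:
    out = rundir / "report.md"
    lines = ["# Phantom cohort analysis report", "",
             "## Configuration", "```yaml", cfg.to_yaml().rstrip(), "```", ""]
    for name in ("fdg_hypo", "fdg_hyper", "fdg_pvc_hypo", "vbm_hypo"):
        path = rundir / "glm" / f"clusters_{name}.tsv"
        if path.exists():
            tab = pd.read_csv(path, sep="\t")
            lines += [f"## Clusters: {name}", "",
                      tab.to_markdown(index=False) if len(tab)
                      else "_no suprathreshold clusters_", ""]
    for f in sorted((rundir / "wscore").glob("freq_summary_*.json")):
        lines += [f"## {f.stem}", "```json", f.read_text().rstrip(), "```",
                  ""]
    summ = rundir / "clinical" / "cohort_summary.tsv"
    if summ.exists():
        lines += ["## Cohort summary", "",
                  pd.read_csv(summ, sep="\t").to_markdown(index=False), ""]
    out.write_text("\n".join(lines))


_STAGE_FUNCS = {
    "simulate": stage_simulate, "pvc": stage_pvc,
    "preprocess": stage_preprocess, "glm": stage_glm,
    "wscore": stage_wscore, "voi": stage_voi,
    "clinical": stage_clinical, "report": stage_report,
}


def run_stage(cfg: RunConfig, rundir, stage: str) -> None:
    if stage not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    try:
        _STAGE_FUNCS[stage](cfg, rundir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc


def run_pipeline(cfg: RunConfig, rundir) -> dict:
    """Run every stage in order; returns a result bundle of output paths."""
    cfg.validate()
    rundir = Path(rundir)
    for stage in STAGES:
        run_stage(cfg, rundir, stage)
    return {
        "rundir": str(rundir),
        "cluster_tables": sorted(str(p) for p in
                                 (rundir / "glm").glob("clusters_*.tsv")),
        "frequency_maps": sorted(str(p) for p in
                                 (rundir / "wscore").glob("freq_*.nii")),
        "cohort_summary": str(rundir / "clinical" / "cohort_summary.tsv"),
        "report": str(rundir / "report.md"),
    }
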