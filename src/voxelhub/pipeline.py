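"""End-to-end orchestration: synth -> preprocess -> DC -> group -> FC -> clinical.

A run is described by a flat YAML/dict config and writes one directory
per stage plus a machine-readable ``run_log.json`` recording the seed,
parameter values and package version.  Any stage failure aborts the run
with the stage name; the log then carries ``status: failed`` and an
``INCOMPLETE`` marker file flags partial outputs.

Large 4-D intermediates (preprocessed BOLD) are held in memory by
default and written to disk only when ``preprocess.save_bold`` is set;
all 3-D maps and tables are always written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    BoldImage,
    CohortTable,
    MaskImage,
    MotionTrace,
    load_bold,
    load_cohort,
    load_map,
    load_mask,
    load_motion,
    save_bold,
    save_map,
    save_mask,
)
from .preprocess import (
    bandpass_filter,
    build_nuisance_design,
    discard_initial_volumes,
    extract_tissue_signal,
    qc_cohort,
    regress_nuisance,
    smooth_gaussian,
)
from .connectome import (
    DEFAULT_THRESHOLDS,
    PRIMARY_THRESHOLD,
    RoiSpec,
    compute_fc,
    dc_multi_threshold,
    extract_roi_timeseries,
)
from .group import (
    compare_demographics,
    extract_cluster_mask,
    grf_cluster_inference,
    make_group_design,
    one_sample_tmap,
    two_sample_glm,
)
from .clinical import clinical_screen, extract_cluster_means
from .synth import HubSpec, SynthSpec, generate_cohort

__all__ = ["PipelineError", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("synth", "preprocess", "dc", "group", "fc", "clinical")

DEFAULTS = {
    "preprocess": {
        "n_discard": 10,
        "band_hz": [0.01, 0.08],
        "smooth_fwhm_mm": 6.0,
        "smooth_stage": "after_dc",   # before_dc | after_dc
        "tr_override": None,
        "save_bold": False,
    },
    "dc": {
        "thresholds": list(DEFAULT_THRESHOLDS),
        "primary": PRIMARY_THRESHOLD,
        "weighted": True,
    },
    "group": {
        "covariates": ["age", "sex", "education"],
        "voxel_p": 0.01,
        "cluster_p": 0.05,
        "connectivity": 26,
    },
    "fc": {"seeds": "from_clusters", "sphere_radius_mm": 6.0},
    "clinical": {"variables": None},
}


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in config.items()}
    for section, defaults in DEFAULTS.items():
        merged = dict(defaults)
        merged.update(cfg.get(section) or {})
        cfg[section] = merged
    return cfg


def _validate(cfg: dict) -> None:
    """Fail before any compute on an unusable config."""
    if "synth" not in cfg:
        inputs = cfg.get("inputs") or {}
        for key in ("cohort", "mask", "bold", "motion"):
            if key not in inputs:
                raise ValueError(f"config missing inputs.{key} (and no synth section)")
    if cfg["preprocess"]["smooth_stage"] not in ("before_dc", "after_dc"):
        raise ValueError("preprocess.smooth_stage must be before_dc or after_dc")
    thr = cfg["dc"]["thresholds"]
    if cfg["dc"]["primary"] not in thr:
        raise ValueError("dc.primary must be one of dc.thresholds")


def _make_synth_spec(section: dict, seed: int) -> SynthSpec:
    section = dict(section or {})
    hubs = section.pop("hubs", None)
    if hubs is not None:
        hubs = [HubSpec(**{**h, "center_mm": tuple(h["center_mm"])}) for h in hubs]
    kwargs = dict(section)
    if hubs is not None:
        kwargs["hubs"] = hubs
    for tup in ("shape",):
        if tup in kwargs:
            kwargs[tup] = tuple(kwargs[tup])
    kwargs["seed"] = seed
    return SynthSpec(**kwargs)


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    stages=STAGES,
) -> Path:
    """Execute the requested stages; returns the output directory.

    ``seed`` overrides the config seed (one seed governs every source of
    randomness; two runs with equal seeds write identical outputs).
    """
    cfg = load_config(config)
    _validate(cfg)
    out = Path(out_dir or cfg.get("out_dir", "voxelhub_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    stages = [s for s in STAGES if s in stages]
    runlog = {
        "package": "voxelhub",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "stages": {},
        "status": "running",
    }
    marker = out / "INCOMPLETE"
    marker.touch()
    state: dict = {}
    try:
        for stage in stages:
            t0 = time.time()
            log.info("stage %s ...", stage)
            _STAGE_FN[stage](cfg, seed, out, state)
            runlog["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
            _write_log(out, runlog)
        runlog["status"] = "complete"
        _write_log(out, runlog)
        marker.unlink(missing_ok=True)
    except PipelineError:
        runlog["status"] = "failed"
        _write_log(out, runlog)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        runlog["status"] = "failed"
        _write_log(out, runlog)
        raise PipelineError(stage, str(exc)) from exc
    return out


def _write_log(out: Path, runlog: dict) -> None:
    with open(out / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth(cfg, seed, out, state):
    if "synth" not in cfg:
        return
    spec = _make_synth_spec(cfg["synth"], seed)
    sdir = out / "synth"
    cohort, manifest = generate_cohort(spec, sdir)
    state["synth_spec"] = spec
    state["inputs"] = {
        "cohort": sdir / "cohort.tsv",
        "mask": sdir / "mask_gm.nii.gz",
        "wm_mask": sdir / "mask_wm.nii.gz",
        "csf_mask": sdir / "mask_csf.nii.gz",
        "bold": {s: sdir / f["bold"] for s, f in manifest["files"].items()},
        "motion": {s: sdir / f["motion"] for s, f in manifest["files"].items()},
    }


def _load_inputs(cfg, out, state):
    if "inputs" in state:
        return
    if "inputs" not in cfg:
        # a synth run restarted mid-way: look for the products on disk
        sdir = out / "synth"
        if not (sdir / "cohort.tsv").exists():
            raise PipelineError("preprocess", "no inputs section and no synth products found")
        with open(sdir / "manifest.json") as fh:
            manifest = json.load(fh)
        state["inputs"] = {
            "cohort": sdir / "cohort.tsv",
            "mask": sdir / "mask_gm.nii.gz",
            "wm_mask": sdir / "mask_wm.nii.gz",
            "csf_mask": sdir / "mask_csf.nii.gz",
            "bold": {s: sdir / f["bold"] for s, f in manifest["files"].items()},
            "motion": {s: sdir / f["motion"] for s, f in manifest["files"].items()},
        }
    else:
        inp = cfg["inputs"]
        state["inputs"] = {
            "cohort": Path(inp["cohort"]),
            "mask": Path(inp["mask"]),
            "wm_mask": Path(inp["wm_mask"]) if inp.get("wm_mask") else None,
            "csf_mask": Path(inp["csf_mask"]) if inp.get("csf_mask") else None,
            "bold": {s: Path(p) for s, p in inp["bold"].items()},
            "motion": {s: Path(p) for s, p in inp["motion"].items()},
        }


def preprocess_subject(
    bold: BoldImage,
    motion: MotionTrace,
    mask: MaskImage,
    wm_mask: MaskImage | None,
    csf_mask: MaskImage | None,
    n_discard: int = 10,
    band_hz=(0.01, 0.08),
    smooth_fwhm_mm: float = 6.0,
    smooth_stage: str = "after_dc",
) -> tuple[BoldImage, MotionTrace]:
    """The per-subject denoising chain (library entry point).

    discard -> nuisance regression (Friston-24 + WM/CSF + intercept +
    trend) -> band-pass; smoothing of the 4-D data happens here only for
    ``smooth_stage='before_dc'`` (otherwise the DC z-map is smoothed at
    the group-prep step instead).
    """
    b = discard_initial_volumes(bold, n_discard)
    m = motion.discard_initial(n_discard) if n_discard else motion
    wm = extract_tissue_signal(b, wm_mask) if wm_mask is not None else None
    csf = extract_tissue_signal(b, csf_mask) if csf_mask is not None else None
    design = build_nuisance_design(m, wm, csf)
    b = regress_nuisance(b, design, mask)
    b = bandpass_filter(b, *band_hz)
    if smooth_stage == "before_dc" and smooth_fwhm_mm > 0:
        b = smooth_gaussian(b, smooth_fwhm_mm)
    return b, m


def _stage_preprocess(cfg, seed, out, state):
    _load_inputs(cfg, out, state)
    inp = state["inputs"]
    p = cfg["preprocess"]
    cohort = load_cohort(inp["cohort"])
    mask = load_mask(inp["mask"])
    wm = load_mask(inp["wm_mask"]) if inp.get("wm_mask") else None
    csf = load_mask(inp["csf_mask"]) if inp.get("csf_mask") else None
    pdir = out / "preprocess"
    pdir.mkdir(exist_ok=True)

    traces = {}
    for sid in cohort.subject_ids:
        traces[sid] = load_motion(inp["motion"][sid]).discard_initial(p["n_discard"])
    reports = qc_cohort(traces)
    qc_df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
    qc_df.to_csv(pdir / "qc_report.tsv", sep="\t", index=False)
    kept = {r.subject_id for r in reports if not r.excluded}
    if len(kept) < len(reports):
        log.warning("excluding %d subject(s) on motion QC", len(reports) - len(kept))

    clean = {}
    for sid in cohort.subject_ids:
        if sid not in kept:
            continue
        bold = load_bold(inp["bold"][sid], tr_override=p["tr_override"])
        b, _ = preprocess_subject(
            bold,
            load_motion(inp["motion"][sid]),
            mask,
            wm,
            csf,
            n_discard=p["n_discard"],
            band_hz=tuple(p["band_hz"]),
            smooth_fwhm_mm=p["smooth_fwhm_mm"],
            smooth_stage=p["smooth_stage"],
        )
        if p["save_bold"]:
            save_bold(b, pdir / f"{sid}_clean.nii.gz")
        clean[sid] = BoldImage(b.data.astype(np.float32), b.affine, b.tr_seconds)
    cohort = CohortTable(cohort.df[cohort.df["subject_id"].isin(kept)])
    state.update(cohort=cohort, mask=mask, clean=clean)


def _stage_dc(cfg, seed, out, state):
    d = cfg["dc"]
    p = cfg["preprocess"]
    mask = state["mask"]
    ddir = out / "dc"
    ddir.mkdir(exist_ok=True)
    zmaps: dict[float, dict[str, np.ndarray]] = {r0: {} for r0 in d["thresholds"]}
    for sid, b in state["clean"].items():
        maps = dc_multi_threshold(
            BoldImage(b.data.astype(np.float64), b.affine, b.tr_seconds),
            mask,
            d["thresholds"],
            weighted=d["weighted"],
        )
        for dm in maps:
            z = dm.z
            if p["smooth_stage"] == "after_dc" and p["smooth_fwhm_mm"] > 0:
                z = smooth_gaussian((z, mask.affine), p["smooth_fwhm_mm"])
            zmaps[dm.r0][sid] = z
            save_map(z, mask.affine, ddir / f"{sid}_dcz_r{dm.r0:.2f}.nii.gz")
    state["dc_zmaps"] = zmaps


def _stage_group(cfg, seed, out, state):
    g = cfg["group"]
    d = cfg["dc"]
    cohort: CohortTable = state["cohort"]
    mask: MaskImage = state["mask"]
    gdir = out / "group"
    gdir.mkdir(exist_ok=True)

    compare_demographics(cohort).to_csv(gdir / "demographics.tsv", sep="\t", index=False)

    design = make_group_design(cohort, covariates=tuple(g["covariates"]))
    sids = cohort.subject_ids
    state["group_tables"] = {}
    for r0, by_sid in state["dc_zmaps"].items():
        maps = [by_sid[s] for s in sids]
        # per-group one-sample hub maps
        for grp in ("patient", "control"):
            sel = [m for m, s in zip(maps, sids) if cohort.group_of(s) == grp]
            res = one_sample_tmap(sel, mask)
            save_map(res.t_map, mask.affine, gdir / f"onesample_{grp}_r{r0:.2f}.nii.gz")
        res = two_sample_glm(maps, design, mask)
        table, labels = grf_cluster_inference(
            res, voxel_p=g["voxel_p"], cluster_p=g["cluster_p"],
            connectivity=g["connectivity"],
        )
        table.to_csv(gdir / f"clusters_r{r0:.2f}.tsv", sep="\t", index=False)
        save_map(res.t_map, mask.affine, gdir / f"twosample_t_r{r0:.2f}.nii.gz")
        save_map(labels, mask.affine, gdir / f"cluster_labels_r{r0:.2f}.nii.gz")
        state["group_tables"][r0] = (table, labels)
    r0 = d["primary"]
    state["primary_clusters"] = state["group_tables"][r0]


def _stage_fc(cfg, seed, out, state):
    f = cfg["fc"]
    g = cfg["group"]
    cohort: CohortTable = state["cohort"]
    mask: MaskImage = state["mask"]
    fdir = out / "fc"
    fdir.mkdir(exist_ok=True)
    table, labels = state["primary_clusters"]

    rois: list[RoiSpec] = []
    if f["seeds"] == "from_clusters":
        for _, row in table.iterrows():
            cm = extract_cluster_mask(labels, int(row["label"]), mask.affine)
            rois.append(RoiSpec(kind="cluster_mask", mask=cm, label=f"cluster{int(row['label'])}"))
    else:
        for s in f["seeds"]:
            rois.append(
                RoiSpec(
                    kind="sphere",
                    center_mm=tuple(s["center_mm"]),
                    radius_mm=float(s.get("radius_mm", f["sphere_radius_mm"])),
                    label=s.get("label", "seed"),
                )
            )
    if not rois:
        log.warning("no significant DC clusters: FC stage has no seeds")
        state["fc_tables"] = {}
        return

    p = cfg["preprocess"]
    design = make_group_design(cohort, covariates=tuple(g["covariates"]))
    sids = cohort.subject_ids
    state["fc_tables"] = {}
    for roi in rois:
        zmaps = []
        for sid in sids:
            b = state["clean"][sid]
            b64 = BoldImage(b.data.astype(np.float64), b.affine, b.tr_seconds)
            ts = extract_roi_timeseries(b64, roi, mask)
            fc = compute_fc(b64, ts, mask, seed_label=roi.label)
            z = fc.z
            if p["smooth_stage"] == "after_dc" and p["smooth_fwhm_mm"] > 0:
                z = smooth_gaussian((z, mask.affine), p["smooth_fwhm_mm"])
            zmaps.append(z)
            save_map(z, mask.affine, fdir / f"{sid}_fcz_{roi.label}.nii.gz")
        res = two_sample_glm(zmaps, design, mask)
        table_fc, labels_fc = grf_cluster_inference(
            res, voxel_p=g["voxel_p"], cluster_p=g["cluster_p"],
            connectivity=g["connectivity"],
        )
        table_fc.to_csv(fdir / f"clusters_{roi.label}.tsv", sep="\t", index=False)
        save_map(res.t_map, mask.affine, fdir / f"twosample_t_{roi.label}.nii.gz")
        state["fc_tables"][roi.label] = table_fc


def _stage_clinical(cfg, seed, out, state):
    c = cfg["clinical"]
    d = cfg["dc"]
    cohort: CohortTable = state["cohort"]
    mask: MaskImage = state["mask"]
    cdir = out / "clinical"
    cdir.mkdir(exist_ok=True)
    table, labels = state["primary_clusters"]
    if table.empty:
        log.warning("no significant DC clusters: clinical stage writes an empty table")
        pd.DataFrame().to_csv(cdir / "clinical_screen.tsv", sep="\t", index=False)
        return
    sids = cohort.subject_ids
    by_sid = state["dc_zmaps"][d["primary"]]
    cm = {"subject_id": sids}
    for _, row in table.iterrows():
        label = int(row["label"])
        cmask = extract_cluster_mask(labels, label, mask.affine)
        cm[f"cluster{label}"] = extract_cluster_means([by_sid[s] for s in sids], cmask)
    cm_df = pd.DataFrame(cm)
    cm_df.to_csv(cdir / "cluster_means.tsv", sep="\t", index=False)
    screen = clinical_screen(cm_df, cohort, variables=c["variables"])
    screen.to_csv(cdir / "clinical_screen.tsv", sep="\t", index=False)
    # scatter data for significant pairs (figure-style plots)
    pats = cohort.subset("patient")
    cm_p = cm_df.set_index("subject_id").loc[pats["subject_id"]]
    for _, row in screen[screen["significant"]].iterrows():
        pd.DataFrame(
            {
                "subject_id": pats["subject_id"],
                row["cluster"]: cm_p[row["cluster"]].to_numpy(),
                row["variable"]: pats[row["variable"]].to_numpy(),
            }
        ).to_csv(cdir / f"scatter_{row['cluster']}_{row['variable']}.tsv", sep="\t", index=False)


_STAGE_FN = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "dc": _stage_dc,
    "group": _stage_group,
    "fc": _stage_fc,
    "clinical": _stage_clinical,
}
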