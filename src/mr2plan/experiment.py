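"""End-to-end experiment driver.

Runs N synthetic animals through the whole MR-only planning workflow:
phantom simulation, bias-field correction, the 31-subset segmentation
sweep scored against the reference segmentation, pseudo-CT synthesis for
the reference and for selected sequence combinations, dose calculation for
three beam arrangements (one static beam through the rostrum, one coplanar
arc, three non-coplanar arcs), DVH metrics normalised to the CT-based
reference, and Mann-Whitney tests across animals.

Per-animal seeds are derived deterministically from the master seed, and a
provenance JSON captures every parameter, so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias_field import ClicParams, apply_correction, estimate_bias
from .dose_engine import (
    ArcSpec,
    BeamSpec,
    PlanSpec,
    TargetSpec,
    plan_dose_raw,
    prescription_scale,
    sphere_voi,
)
from .dvh_analysis import (
    aggregate_ratios,
    compare_to_ct,
    dose_metrics,
    mann_whitney,
)
from .fcm_segmentation import (
    FcmParams,
    canonical_subset,
    make_air_mask,
    subset_name,
    sweep_combinations,
)
from .phantom import PhantomSpec, default_sequence_models, generate_phantom
from .pseudo_ct import assign_properties
from .similarity import aggregate_dice, evaluate_sweep, reports_to_frame
log = logging.getLogger(__name__)

DEFAULT_METHODS = (("ZTE", "UTE2"), ("T1", "UTE1", "T2"), ("UTE1", "UTE2"))


class ExperimentError(RuntimeError):
    """A stage failed; carries the stage name and animal index."""

    def __init__(self, stage: str, animal: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed for animal {animal}: {cause}")
        self.stage = stage
        self.animal = animal
        self.cause = cause


@dataclass(frozen=True)
class ExperimentConfig:
    n_animals: int = 6
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    noise_fraction: float = 0.05
    bias_amplitude: float = 0.3
    bias_correction: bool = True
    clic: ClicParams = field(default_factory=ClicParams)
    fcm: FcmParams = field(default_factory=FcmParams)
    methods: tuple[tuple[str, ...], ...] = DEFAULT_METHODS
    target_offset: tuple[float, float, float] = (0.0, 6.0, 3.0)
    target_diameter: float = 2.5
    field_size: tuple[float, float] = (3.0, 3.0)
    sad: float = 350.0
    angular_step: float = 5.0
    prescription_dose: float = 15.0
    master_seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for m in self.methods:
            canonical_subset(m)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["phantom"].items()
            })
        if "clic" in kwargs:
            kwargs["clic"] = ClicParams(**kwargs["clic"])
        if "fcm" in kwargs:
            kwargs["fcm"] = FcmParams(**kwargs["fcm"])
        for key in ("methods",):
            if key in kwargs:
                kwargs[key] = tuple(tuple(m) for m in kwargs[key])
        for key in ("target_offset", "field_size"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def animal_seed(master_seed: int, animal: int) -> int:
    """Deterministic per-animal seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(animal)])
    return int(ss.generate_state(1)[0] % (2**31))


def build_plans(config: ExperimentConfig, target_center) -> dict[str, PlanSpec]:
    """The three beam arrangements aimed at the target.

    The single static beam enters anteriorly (through the rostrum), where
    MR segmentation errors are expected to matter most; the arcs rotate the
    gantry 120 degrees at couch 0 (one arc) or couch 0/45/90 (three arcs).
    """
    iso = tuple(float(c) for c in target_center)
    target = TargetSpec(center=iso, diameter=config.target_diameter)
    common = dict(isocenter=iso, field_size=config.field_size, source_axis_distance=config.sad)
    one_beam = PlanSpec(
        segments=(BeamSpec(gantry_angle=90.0, couch_angle=90.0, **common),),
        target=target,
        prescription_dose=config.prescription_dose,
    )
    one_arc = PlanSpec(
        segments=(ArcSpec(couch_angle=0.0, angular_step=config.angular_step, **common),),
        target=target,
        prescription_dose=config.prescription_dose,
    )
    three_arcs = PlanSpec(
        segments=tuple(
            ArcSpec(couch_angle=c, angular_step=config.angular_step, **common)
            for c in (0.0, 45.0, 90.0)
        ),
        target=target,
        prescription_dose=config.prescription_dose,
    )
    return {"1_beam": one_beam, "1_arc": one_arc, "3_arcs": three_arcs}


def _stage(stage: str, animal: int):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise ExperimentError(stage, animal, exc) from exc
            log.info("animal=%d stage=%s elapsed=%.1fs", animal, stage, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_animal(config: ExperimentConfig, animal: int) -> dict:
    """Run the full workflow for one synthetic animal."""
    seed = animal_seed(config.master_seed, animal)
    models = default_sequence_models(config.noise_fraction, config.bias_amplitude)
    spec = replace(config.phantom, seed=seed)

    with _stage("phantom", animal):
        truth = generate_phantom(spec, models)

    with _stage("bias_correction", animal):
        if config.bias_correction:
            head = make_air_mask(truth.noisy_images["T1"])
            images = {}
            for name, img in truth.noisy_images.items():
                state = estimate_bias(img, head, config.clic)
                images[name] = apply_correction(img, state, head)
        else:
            images = dict(truth.noisy_images)

    with _stage("air_mask", animal):
        air_mask = make_air_mask(images["T1"])

    with _stage("segmentation_sweep", animal):
        asmr_list = sweep_combinations(images, air_mask, config.fcm)

    reference = truth.labels  # stands in for the manually segmented CT
    with _stage("dice", animal):
        reports = evaluate_sweep(reference, asmr_list)
        dice_frame = reports_to_frame(reports)
        dice_frame.insert(0, "animal", animal)

    with _stage("planning", animal):
        target_center = tuple(c + o for c, o in zip(spec.center, config.target_offset))
        plans = build_plans(config, target_center)
        props_ct = assign_properties(reference)
        ct_metrics = {}
        scales = {}
        abs_rows = []
        for config_name, plan in plans.items():
            raw = plan_dose_raw(props_ct, plan)
            scale = prescription_scale(raw, plan)
            scales[config_name] = scale
            dose = raw.like(raw.data * scale)
            voi = sphere_voi(plan.target.center, plan.target.diameter, dose)
            ct_metrics[config_name] = dose_metrics(dose, voi)
            abs_rows.append(
                {"animal": animal, "method": "CT", "configuration": config_name,
                 **{k: v for k, v in ct_metrics[config_name].as_dict().items()}}
            )

        by_combo = {subset_name(a.combination): a for a in asmr_list}
        mr_metrics = {}
        for method in config.methods:
            name = subset_name(method)
            asmr = by_combo[name]
            props_mr = assign_properties(asmr.labels)
            per_config = {}
            for config_name, plan in plans.items():
                raw = plan_dose_raw(props_mr, plan)
                dose = raw.like(raw.data * scales[config_name])
                voi = sphere_voi(plan.target.center, plan.target.diameter, dose)
                per_config[config_name] = dose_metrics(dose, voi)
                abs_rows.append(
                    {"animal": animal, "method": name, "configuration": config_name,
                     **per_config[config_name].as_dict()}
                )
            mr_metrics[name] = per_config

        ratios = compare_to_ct(ct_metrics, mr_metrics)
        ratios.insert(0, "animal", animal)

    return {
        "dice": dice_frame,
        "ratios": ratios,
        "metrics": pd.DataFrame(abs_rows),
        "seed": seed,
    }


def run_experiment(config: ExperimentConfig, outdir: str | None = None) -> dict:
    """Run all animals and assemble the report bundle.

    Returns a dict of DataFrames (``dice_sweep``, ``dice_aggregate``,
    ``dose_metrics``, ``dose_ratios_aggregate``, ``mann_whitney``) plus
    provenance; writes CSVs and provenance JSON if ``outdir`` is given.
    """
    per_animal = [run_animal(config, a) for a in range(config.n_animals)]

    dice_frames = [r["dice"] for r in per_animal]
    dice_sweep = pd.concat(dice_frames, ignore_index=True)
    dice_aggregate = aggregate_dice(dice_frames)

    metrics = pd.concat([r["metrics"] for r in per_animal], ignore_index=True)
    ratio_frames = [r["ratios"] for r in per_animal]
    ratios = pd.concat(ratio_frames, ignore_index=True)
    ratios_aggregate = aggregate_ratios(ratio_frames)

    mw_rows = []
    if config.n_animals >= 2:
        for method in sorted(metrics.method.unique()):
            if method == "CT":
                continue
            for config_name in sorted(metrics.configuration.unique()):
                for metric in ("D5", "D50", "D90"):
                    ct_vals = metrics.query("method == 'CT' and configuration == @config_name")[metric]
                    mr_vals = metrics.query("method == @method and configuration == @config_name")[metric]
                    u, p = mann_whitney(mr_vals.to_numpy(), ct_vals.to_numpy())
                    mw_rows.append(
                        {"method": method, "configuration": config_name, "metric": metric,
                         "U": u, "p_value": p, "significant_at_0.05": bool(p < 0.05)}
                    )
    mann_whitney_table = pd.DataFrame(mw_rows)

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "animal_seeds": [r["seed"] for r in per_animal],
    }

    bundle = {
        "dice_sweep": dice_sweep,
        "dice_aggregate": dice_aggregate,
        "dose_metrics": metrics,
        "dose_ratios": ratios,
        "dose_ratios_aggregate": ratios_aggregate,
        "mann_whitney": mann_whitney_table,
        "provenance": provenance,
    }

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        dice_sweep.to_csv(os.path.join(outdir, "dice_sweep.csv"), index=False)
        dice_aggregate.to_csv(os.path.join(outdir, "dice_aggregate.csv"), index=False)
        metrics.to_csv(os.path.join(outdir, "dose_metrics.csv"), index=False)
        ratios.to_csv(os.path.join(outdir, "dose_ratios.csv"), index=False)
        ratios_aggregate.to_csv(os.path.join(outdir, "dose_ratios_aggregate.csv"), index=False)
        mann_whitney_table.to_csv(os.path.join(outdir, "mann_whitney.csv"), index=False)
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return bundle
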