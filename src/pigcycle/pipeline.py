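"""End-to-end orchestration: masks -> features -> weights -> plans -> footprint.

``run_pipeline`` drives the whole closed loop on disk artifacts and writes
a manifest with SHA-256 hashes of every input and output, so two runs
with the same config and inputs are verifiably identical.
``compare_scenarios`` is the pure arithmetic comparing a baseline and an
optimized footprint on the same functional unit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import feeding, weight
from .lca import ActivityLedger, EmissionFactorSet, FootprintBreakdown, footprint_from_ledger
from .morphometrics import extract_directory

__all__ = ["RunConfig", "run_pipeline", "compare_scenarios"]

DEFAULT_ALLOWANCE = {10.0: 0.6, 30.0: 1.4, 80.0: 2.6, 120.0: 3.2}


@dataclass
class RunConfig:
    mask_dir: Path
    weights_csv: Path  # columns: pig_id, mask_id, day, observed_weight
    ledger_dir: Path
    out_dir: Path
    factors: EmissionFactorSet = field(default_factory=EmissionFactorSet)
    seed: int = 0
    closing_radius: int = 3
    scale: float = 1.0
    squared_eccentricity: bool = False
    test_fraction: float = 0.2
    grid: weight.SearchGrid | None = None
    stage_table: feeding.StageTable = field(default_factory=lambda: feeding.DEFAULT_STAGE_TABLE)
    allowance_table: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_ALLOWANCE))

    def validate(self) -> None:
        for label, p in (
            ("mask directory", self.mask_dir),
            ("weights CSV", self.weights_csv),
            ("ledger directory", self.ledger_dir),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    # fixed float formatting keeps re-runs byte-identical
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> fit/predict -> plan -> footprint; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(
            {
                "seed": config.seed,
                "closing_radius": config.closing_radius,
                "scale": config.scale,
                "squared_eccentricity": config.squared_eccentricity,
                "test_fraction": config.test_fraction,
                "allowance_table": sorted(config.allowance_table.items()),
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # 1. morphometrics
    features = stage(
        "features",
        lambda: extract_directory(
            config.mask_dir,
            closing_radius=config.closing_radius,
            scale=config.scale,
            squared_eccentricity=config.squared_eccentricity,
        ),
    )
    _write_csv(features, out / "features.csv", config_hash)

    # 2. weight model
    weights_df = pd.read_csv(config.weights_csv)
    records = stage("join", lambda: features.merge(weights_df, on="mask_id", how="inner"))
    if records.empty:
        raise RuntimeError("pipeline stage 'join' failed: no mask_id overlap between features and weights")
    train, test = stage(
        "split", lambda: weight.split_by_pig(records, config.test_fraction, config.seed)
    )
    grid = config.grid or weight.SearchGrid.small(seed=config.seed)
    model = stage("fit", lambda: weight.fit(train, grid))
    preds = weight.predict(model, test)
    report = weight.evaluate(
        preds, test["observed_weight"].to_numpy(), model.feature_importances()
    )
    report.to_json(out / "eval_report.json")
    pred_df = test[["mask_id", "pig_id", "day", "observed_weight"]].copy()
    pred_df["estimated_weight"] = preds
    _write_csv(pred_df, out / "predictions.csv", config_hash)

    # 3. feeding plans from per-pig estimated trajectories
    plans = []
    all_preds = weight.predict(model, records)
    traj = records[["mask_id", "pig_id", "day"]].copy()
    traj["estimated_weight"] = all_preds
    for pig_id, grp in traj.groupby("pig_id"):
        grp = grp.sort_values("day")
        w_now = float(grp["estimated_weight"].iloc[-1])
        adg = (
            feeding.daily_gain(grp["day"].to_numpy(), grp["estimated_weight"].to_numpy())
            if len(grp) >= 2
            else float("nan")
        )
        label = feeding.classify_stage(w_now, config.stage_table)
        base = feeding.stage_ration(label, config.stage_table)
        ration = feeding.adjust_ration(base, w_now, adg) if np.isfinite(adg) else base
        qty = feeding.plan_feed_quantity(w_now, config.allowance_table)
        plans.append(
            {
                "pig_id": pig_id,
                "day": int(grp["day"].iloc[-1]),
                "estimated_weight": w_now,
                "adg": adg,
                "stage": label,
                **{k: v for k, v in ration.components().items()},
                "feeds_per_day": ration.feeds_per_day,
                "kg_per_day": qty,
            }
        )
    plans_df = pd.DataFrame(plans).sort_values("pig_id")
    _write_csv(plans_df, out / "feeding_plans.csv", config_hash)

    # 4. carbon footprint
    ledger = stage("ledger", lambda: ActivityLedger.from_csv_dir(config.ledger_dir))
    breakdown = stage("footprint", lambda: footprint_from_ledger(ledger, config.factors))
    breakdown.to_json(out / "footprint.json")

    manifest = {
        "config_hash": config_hash,
        "seed": config.seed,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.name != "manifest.json"
        },
        "inputs": {
            "weights_csv": _sha256(Path(config.weights_csv)),
            "n_masks": len(features),
        },
        "eval": {"MAE": report.MAE, "R2": report.R2},
        "cf_per_kg": breakdown.cf_per_kg,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def compare_scenarios(
    baseline: FootprintBreakdown, optimized: FootprintBreakdown
) -> dict[str, float]:
    """Percentage reductions, component by component and in total.

    Both breakdowns must be normalised to the same functional unit (same
    live-weight basis); reductions are (base - opt) / base x 100.
    """
    if not np.isclose(baseline.live_weight, optimized.live_weight):
        raise ValueError(
            "scenario comparison requires the same functional unit: "
            f"live weights {baseline.live_weight} vs {optimized.live_weight}"
        )
    out = {}
    base_comps = baseline.components()
    opt_comps = optimized.components()
    for key, base_val in base_comps.items():
        out[f"{key}_reduction_pct"] = (
            (base_val - opt_comps[key]) / base_val * 100.0 if base_val else 0.0
        )
    out["total_reduction_pct"] = (
        (baseline.cf_total - optimized.cf_total) / baseline.cf_total * 100.0
        if baseline.cf_total
        else 0.0
    )
    out["per_kg_reduction_pct"] = (
        (baseline.cf_per_kg - optimized.cf_per_kg) / baseline.cf_per_kg * 100.0
        if baseline.cf_per_kg
        else 0.0
    )
    return out
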