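"""Calibrate and package the synthetic-cohort scenarios.

Three calibrations are computed once here and shipped inside the
scenario YAML files under ``src/schemagaze/scenarios/``:

1. the encoding-fixation schema-mixing weight lambda, bisected until the
   manipulation-check mean fixation-probability correlation hits each
   experiment's target (0.354 for the Exp-2 design, 0.273 for Exp-1);
2. the latent schema-use slopes g_pred/g_prob of the retrieval-gaze
   model.  The planted targets are defined on the *measured* z-scored
   schema index, so the raw latent slopes must be inflated by the
   attenuation of the mixture + finite-fixation measurement chain,
   estimated from a pilot cohort;
3. the direct memory-model coefficients of the ``full_calibrated``
   scenario, iterated so that the marginal memory fit (which omits the
   schema index) recovers the target coefficients even though part of
   the planted effect flows through the schema pathway.

Run from the repository root:  python analysis/02_calibrate_scenarios.py
(takes a few minutes; output YAMLs are versioned artifacts).
"""

import json
import sys
from pathlib import Path

import numpy as np
import yaml

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from schemagaze.cohort import (
    LinearOutcomeCfg,
    ResponseModelCfg,
    RetrievalGazeCfg,
    ScenarioConfig,
    calibrate_fixation_mixing,
    generate_cohort,
)
from schemagaze.stats import fit_linear_outcome, fit_memory_model

OUT = ROOT / "src/schemagaze/scenarios"
RESULTS = ROOT / "results"

# Target effect sizes planted by the scenarios (per-SD coefficients and
# cohort-level moments as reported for the two experiments).
EXP2 = dict(
    corr=0.354, acc=0.55, b_prob=0.379, b_pred=0.334,
    conf=(6.11, 0.258, 0.111), rt=(7.34, -0.268, -0.170, 2.0),
    g_pred=-0.18, g_prob=-0.003, b_w=-1.18, c_w=-0.38, r_w=0.36,
)
EXP1 = dict(
    corr=0.273, acc=0.49, b_prob=0.233, b_pred=0.289,
    conf=(5.65, 0.09, 0.159), rt=(8.3, -0.200, -0.362, 2.9),
)


def base_cfg(design: str) -> ScenarioConfig:
    if design == "exp2":
        return ScenarioConfig(design="exp2", n_subjects=95, preview_s=8.0)
    return ScenarioConfig(design="exp1", n_subjects=37, preview_s=10.0)


def write_scenario(cfg: ScenarioConfig, note: str) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / f"{cfg.name}.yaml"
    header = "".join(f"# {line}\n" for line in note.strip().splitlines())
    path.write_text(header + yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    print(f"wrote {path}")


def main():
    rng_probe = 20240801
    report = {}

    # -- 1. lambda calibration per design ---------------------------------
    lam2, r2 = calibrate_fixation_mixing(
        base_cfg("exp2"), EXP2["corr"], n_subjects=48, tol=0.006
    )
    print(f"exp2 lambda={lam2:.4f} achieved r={r2:.4f}")
    lam1, r1 = calibrate_fixation_mixing(
        base_cfg("exp1"), EXP1["corr"], n_subjects=48, tol=0.006
    )
    print(f"exp1 lambda={lam1:.4f} achieved r={r1:.4f}")
    report["lambda"] = {"exp2": [lam2, r2], "exp1": [lam1, r1]}

    # -- 2. retrieval-gaze attenuation ------------------------------------
    # Pilot cohort with the raw slopes set to the targets; the recovered
    # slope over the planted one estimates the attenuation rho.
    # Secant iteration on full-size pilots (two seeds averaged per
    # evaluation) because the recovery target has a ~0.012 SE at the
    # design n and the clipping makes the chain mildly nonlinear.
    g_pred_t, g_prob_t = EXP2["g_pred"], EXP2["g_prob"]
    hist_att = []

    def recovered_slope(g_pred_raw: float) -> float:
        scale = g_pred_raw / g_pred_t
        got = []
        for off in range(2):
            pilot = base_cfg("exp2")
            pilot.name = "pilot_attenuation"
            pilot.fixation.lambda_enc = lam2
            pilot.retrieval = RetrievalGazeCfg(
                g_pred=float(g_pred_raw), g_prob=float(g_prob_t * scale),
                sigma_w=float(np.sqrt(max(1 - g_pred_raw**2, 0.05))),
            )
            ds = generate_cohort(pilot, seed=rng_probe + 1000 * off)
            fit = fit_linear_outcome(
                ds.trials, "w_moveProb_z", ("pred_acc_z", "move_logprob_z"),
                include_interaction=True, drop_flagged="w_flag",
            )
            got.append(fit["pred_acc_z"]["coef"])
        mean = float(np.mean(got))
        hist_att.append([g_pred_raw, got, mean])
        print(f"attenuation probe: raw {g_pred_raw:.4f} -> recovered "
              f"{got[0]:.4f}, {got[1]:.4f} (mean {mean:.4f})")
        return mean

    g_a, g_b = -0.24, -0.32
    r_a, r_b = recovered_slope(g_a), recovered_slope(g_b)
    for _ in range(3):
        if abs(r_b - r_a) < 1e-4:
            break
        g_new = g_a + (g_pred_t - r_a) * (g_b - g_a) / (r_b - r_a)
        g_new = float(np.clip(g_new, -0.6, -0.05))
        r_new = recovered_slope(g_new)
        if abs(r_new - g_pred_t) <= 0.008:
            g_a, r_a = g_new, r_new
            break
        g_a, r_a, g_b, r_b = g_new, r_new, g_a, r_a
    g_pred_raw = g_a if abs(r_a - g_pred_t) <= abs(r_b - g_pred_t) else g_b
    g_prob_raw = g_prob_t * (g_pred_raw / g_pred_t)
    sigma_w = float(np.sqrt(max(1 - g_pred_raw**2 - g_prob_raw**2, 0.05)))
    report["attenuation"] = {"history": hist_att, "g_pred_raw": g_pred_raw,
                             "g_prob_raw": g_prob_raw}
    retrieval_cal = RetrievalGazeCfg(
        g_pred=float(g_pred_raw), g_prob=float(g_prob_raw), sigma_w=sigma_w
    )

    # -- scenario definitions ---------------------------------------------
    def linear(intercept, b_prob, b_pred, sigma_e=1.5, b_w=0.0, floor=None,
               sigma_u=0.9):
        return LinearOutcomeCfg(intercept=intercept, b_prob=b_prob,
                                b_pred=b_pred, b_w=b_w, sigma_u=sigma_u,
                                sigma_e=sigma_e, floor=floor)

    exp2_marginal = base_cfg("exp2")
    exp2_marginal.name = "exp2_marginal"
    exp2_marginal.target_corr = EXP2["corr"]
    exp2_marginal.fixation.lambda_enc = float(lam2)
    exp2_marginal.response = ResponseModelCfg(
        target_accuracy=EXP2["acc"], b_prob=EXP2["b_prob"],
        b_pred=EXP2["b_pred"], b_inter=0.0, b_w=0.0, sigma_u=0.5,
    )
    exp2_marginal.confidence = linear(*EXP2["conf"])
    r0, rp, rq, rse = EXP2["rt"]
    exp2_marginal.rt = linear(r0, rp, rq, sigma_e=rse, floor=0.5, sigma_u=1.2)
    exp2_marginal.retrieval = retrieval_cal
    write_scenario(
        exp2_marginal,
        "Exp-2 marginal-effects scenario: planted memory coefficients are the\n"
        "reported marginal fits; the schema index carries no additional\n"
        "effect on accuracy (b_w = 0).  lambda_enc calibrated to a mean\n"
        "fixation-probability correlation of 0.354.",
    )

    exp1_marginal = base_cfg("exp1")
    exp1_marginal.name = "exp1_marginal"
    exp1_marginal.target_corr = EXP1["corr"]
    exp1_marginal.fixation.lambda_enc = float(lam1)
    exp1_marginal.response = ResponseModelCfg(
        target_accuracy=EXP1["acc"], b_prob=EXP1["b_prob"],
        b_pred=EXP1["b_pred"], b_inter=0.0, b_w=0.0, sigma_u=0.5,
    )
    exp1_marginal.confidence = linear(*EXP1["conf"])
    r0, rp, rq, rse = EXP1["rt"]
    exp1_marginal.rt = linear(r0, rp, rq, sigma_e=rse, floor=0.5, sigma_u=1.5)
    exp1_marginal.retrieval = retrieval_cal
    write_scenario(
        exp1_marginal,
        "Exp-1 marginal-effects scenario (four-condition design, 10-s preview,\n"
        "37 subjects).  lambda_enc calibrated to a mean correlation of 0.273.",
    )

    exp2_schema = base_cfg("exp2")
    exp2_schema.name = "exp2_schema_pathway"
    exp2_schema.target_corr = EXP2["corr"]
    exp2_schema.fixation.lambda_enc = float(lam2)
    exp2_schema.response = ResponseModelCfg(
        target_accuracy=EXP2["acc"], b_prob=0.0, b_pred=0.0, b_inter=0.0,
        b_w=EXP2["b_w"], sigma_u=0.5,
    )
    exp2_schema.confidence = linear(*EXP2["conf"], b_w=EXP2["c_w"])
    r0, rp, rq, rse = EXP2["rt"]
    exp2_schema.rt = linear(r0, rp, rq, sigma_e=rse, b_w=EXP2["r_w"],
                            floor=0.5, sigma_u=1.2)
    exp2_schema.retrieval = retrieval_cal
    write_scenario(
        exp2_schema,
        "Exp-2 schema-pathway scenario: accuracy is driven only by the\n"
        "measured schema-use index (b_w = -1.18); prediction accuracy lowers\n"
        "latent schema use (g_pred targets -0.18 on the measured index after\n"
        "attenuation calibration), producing the mediated pathway.",
    )

    exp2_confidence = base_cfg("exp2")
    exp2_confidence.name = "exp2_confidence"
    exp2_confidence.target_corr = EXP2["corr"]
    exp2_confidence.fixation.lambda_enc = float(lam2)
    exp2_confidence.response = ResponseModelCfg(
        target_accuracy=EXP2["acc"], b_prob=0.0, b_pred=0.0,
        b_w=EXP2["b_w"], sigma_u=0.5,
    )
    exp2_confidence.confidence = linear(*EXP2["conf"], b_w=EXP2["c_w"])
    exp2_confidence.rt = linear(EXP2["rt"][0], EXP2["rt"][1], EXP2["rt"][2],
                                sigma_e=EXP2["rt"][3], b_w=EXP2["r_w"],
                                floor=0.5, sigma_u=1.2)
    exp2_confidence.retrieval = retrieval_cal
    write_scenario(
        exp2_confidence,
        "Exp-2 confidence/RT scenario: schema use at retrieval lowers\n"
        "confidence (c_w = -0.38) and slows responses (r_w = 0.36) on top of\n"
        "the marginal confidence and RT effects.",
    )

    exp2_null = base_cfg("exp2")
    exp2_null.name = "exp2_null"
    exp2_null.target_corr = EXP2["corr"]
    exp2_null.fixation.lambda_enc = float(lam2)
    exp2_null.response = ResponseModelCfg(target_accuracy=EXP2["acc"],
                                          sigma_u=0.5)
    exp2_null.confidence = linear(EXP2["conf"][0], 0.0, 0.0)
    exp2_null.rt = linear(EXP2["rt"][0], 0.0, 0.0, sigma_e=EXP2["rt"][3],
                          floor=0.5, sigma_u=1.2)
    exp2_null.retrieval = RetrievalGazeCfg(sigma_w=1.0)
    write_scenario(
        exp2_null,
        "Exp-2 null scenario: every planted effect is zero; used for type-I\n"
        "error and false-positive checks.",
    )

    # -- 3. full_calibrated self-consistency ------------------------------
    full = base_cfg("exp2")
    full.name = "full_calibrated"
    full.target_corr = EXP2["corr"]
    full.fixation.lambda_enc = float(lam2)
    full.retrieval = retrieval_cal
    full.confidence = linear(*EXP2["conf"], b_w=EXP2["c_w"])
    full.rt = linear(EXP2["rt"][0], EXP2["rt"][1], EXP2["rt"][2],
                     sigma_e=EXP2["rt"][3], b_w=EXP2["r_w"], floor=0.5,
                     sigma_u=1.2)
    direct_prob, direct_pred = EXP2["b_prob"], EXP2["b_pred"]
    hist = []
    for it in range(3):
        full.response = ResponseModelCfg(
            target_accuracy=EXP2["acc"], b_prob=float(direct_prob),
            b_pred=float(direct_pred), b_w=EXP2["b_w"], sigma_u=0.5,
        )
        ds = generate_cohort(full, seed=rng_probe + it)
        fit = fit_memory_model(ds.trials, random_slopes=())
        got_prob = fit["move_logprob_z"]["coef"]
        got_pred = fit["pred_acc_z"]["coef"]
        hist.append([direct_prob, direct_pred, got_prob, got_pred])
        print(f"iter {it}: direct ({direct_prob:.3f},{direct_pred:.3f}) -> "
              f"marginal ({got_prob:.3f},{got_pred:.3f})")
        direct_prob += EXP2["b_prob"] - got_prob
        direct_pred += EXP2["b_pred"] - got_pred
    full.response = ResponseModelCfg(
        target_accuracy=EXP2["acc"], b_prob=float(direct_prob),
        b_pred=float(direct_pred), b_w=EXP2["b_w"], sigma_u=0.5,
    )
    write_scenario(
        full,
        "Exp-2 scenario with every pathway active.  Direct memory\n"
        "coefficients are self-consistency calibrated so the marginal memory\n"
        "fit recovers the target coefficients even though part of the\n"
        "planted effect flows through the schema-use pathway.",
    )
    report["full_calibrated"] = {"direct_prob": direct_prob,
                                 "direct_pred": direct_pred, "history": hist}

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "scenario_calibration.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    print("calibration report -> results/scenario_calibration.json")


if __name__ == "__main__":
    main()
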