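"""Recovery metrics comparing pipeline estimates against generator truth."""

from __future__ import annotations

import numpy as np

from .cohort import Cohort


def subspace_angle_deg(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """Largest principal angle (degrees) between two row-spanned subspaces."""
    Qa = np.linalg.qr(np.asarray(basis_a, dtype=float).T)[0]
    Qb = np.linalg.qr(np.asarray(basis_b, dtype=float).T)[0]
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    s = np.clip(s, -1.0, 1.0)
    return float(np.degrees(np.arccos(s.min())))


def truth_report(cohort: Cohort, estimates: dict) -> dict:
    """One table of recovery errors per supplied pipeline-stage estimate.

    Recognized ``estimates`` keys:

    - ``fstd_point_mean``: (k,) estimated per-point mean depth (mm)
    - ``rv_nose`` / ``rv_mouth``: estimated RV coefficients
    - ``nose_map`` / ``mouth_map``: fitted score-map matrices paired with
      ``*_map_truth`` references
    - ``ssm_basis``: (d, 3k) estimated SSM basis with ``ssm_basis_truth``
    """
    report: dict[str, dict] = {}
    truth = cohort.truth
    if "fstd_point_mean" in estimates:
        est = np.asarray(estimates["fstd_point_mean"], dtype=float)
        true_mean = truth.depth_fields.mean(axis=0)
        ok = np.isfinite(est)
        err = np.abs(est[ok] - true_mean[ok])
        report["fstd"] = {
            "mean_abs_error_mm": float(err.mean()),
            "p95_abs_error_mm": float(np.quantile(err, 0.95)),
            "n_points": int(ok.sum()),
        }
    for organ in ("nose", "mouth"):
        key = f"rv_{organ}"
        if key in estimates:
            report[key] = {
                "estimated_rv": float(estimates[key]),
                "generator_rho": float(cohort.spec.organ_rho),
            }
        mkey = f"{organ}_map"
        if mkey in estimates and f"{mkey}_truth" in estimates:
            M = np.asarray(estimates[mkey], dtype=float)
            Mt = np.asarray(estimates[f"{mkey}_truth"], dtype=float)
            denom = np.linalg.norm(Mt)
            report[mkey] = {
                "relative_frobenius_error": (
                    float(np.linalg.norm(M - Mt) / denom) if denom > 0 else np.inf
                )
            }
    if "ssm_basis" in estimates and "ssm_basis_truth" in estimates:
        report["ssm"] = {
            "max_principal_angle_deg": subspace_angle_deg(
                estimates["ssm_basis"], estimates["ssm_basis_truth"]
            )
        }
    return report
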