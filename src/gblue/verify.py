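"""Property-based verification battery.

Each check simulates fresh instances of the whole-genome regression model
and measures an algebraic identity or statistical property against an
independent dense-algebra oracle:

1. BLUE invariance — GLS under V2 equals GLS under V12 (both covariances
   built and inverted densely and separately).
2. Woodbury down-date — the rank-p1 identity for V2⁻¹ matches dense
   inversion of V12 − X1X1'σβ².
3. Variance adjustment — (X1'V12⁻¹X1)⁻¹ − Iσβ² equals (X1'V2⁻¹X1)⁻¹, and
   naive − adjusted equals σβ²I.
4. BLUP-zero — the double-counted MME solution has β→1 = 0 and its
   (α̂, β→2) match the reduced model that excludes X1 from the random part.
5. Correlated blocks — β→1 + C·β→2 = 0 for the coupling block C of the
   inverted prior metric, and the fixed-effect solutions with/without the
   cross-covariance genuinely differ (invariance failure).
6. Conditional model — Schur complement, signal decomposition and the
   zero-residual BLUP(δ) identity.
7. Calibration — the Wald test with the adjusted variance attains nominal
   size under the null; the naive variance is no more liberal.
8. Scan strategy equivalence — reuse-v12 and per-set-v2 full scans agree.

MME identity checks use the *direct* dense solve of the full printed
system so the zero/coupling results are emergent, not imposed by the
solver's algebraic reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import spd_inverse, symmetrize
from .conditional import (
    conditional_blup_delta,
    conditional_design,
    conditional_gls,
)
from .covariance import build_covariances, woodbury_downdate_inverse
from .datatypes import EffectCovariance, VarianceComponents
from .gls import adjusted_variance, gls_estimate, wald_test
from .mme import build_mme, reduced_mme, solve_mme, solve_mme_correlated
from .scan import ScanConfig, run_scan
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "CheckResult",
    "check_blue_invariance",
    "check_woodbury",
    "check_variance_adjustment",
    "check_blup_zero",
    "check_correlated_blocks",
    "check_conditional_model",
    "check_calibration",
    "check_scan_equivalence",
    "run_all_checks",
]


@dataclass
class CheckResult:
    name: str
    passed: bool
    metrics: dict
    n: int  # problem size / replicate count the check actually used


def _instance_grid(seed: int, n_instances: int):
    """Random instance parameters spanning the verification grid."""
    rng = np.random.default_rng(seed)
    variances = np.array([0.1, 1.0, 10.0])
    for _ in range(n_instances):
        n = int(rng.integers(20, 101))
        p = int(rng.integers(2 * n, max(2 * n + 1, min(500, 5 * n))))
        p1 = int(rng.integers(1, 6))
        sb2 = float(rng.choice(variances))
        se2 = float(rng.choice(variances))
        yield n, p, p1, sb2, se2, int(rng.integers(0, 2**31 - 1))


def _simulated_instance(n, p, p1, sb2, se2, seed):
    cfg = SimulationConfig(
        n_samples=n,
        n_markers=p,
        sigma_beta2=sb2,
        sigma_e2=se2,
        fixed_alpha=0.5 * np.ones(p1),
        seed=seed,
    )
    geno, pheno, _ = simulate_dataset(cfg, p1=p1)
    part = geno.partition(list(range(p1)))
    vc = VarianceComponents(sb2, se2)
    return geno, pheno, part, vc


def check_blue_invariance(seed: int, n_instances: int = 50) -> CheckResult:
    """BLUE under V2 equals BLUE under V12, dense oracle on both paths."""
    worst = 0.0
    for n, p, p1, sb2, se2, s in _instance_grid(seed, n_instances):
        geno, pheno, part, vc = _simulated_instance(n, p, p1, sb2, se2, s)
        model = build_covariances(geno, part, vc)
        x1, _ = geno.split(part)
        est_v2 = gls_estimate(x1, spd_inverse(model.V2), pheno.values)
        est_v12 = gls_estimate(x1, spd_inverse(model.V12), pheno.values)
        worst = max(worst, float(np.abs(est_v2 - est_v12).max()))
    return CheckResult(
        "blue_invariance",
        worst < 1e-8,
        {"max_abs_diff": worst, "tolerance": 1e-8},
        n_instances,
    )


def check_woodbury(seed: int, n_instances: int = 20) -> CheckResult:
    """Down-date V2⁻¹ vs dense inversion of V12 − X1X1'σβ²."""
    worst = 0.0
    for n, p, p1, sb2, se2, s in _instance_grid(seed, n_instances):
        geno, pheno, part, vc = _simulated_instance(n, p, p1, sb2, se2, s)
        model = build_covariances(geno, part, vc)
        x1, _ = geno.split(part)
        v12_inv = spd_inverse(model.V12)
        v2_inv_wb = woodbury_downdate_inverse(v12_inv, x1, sb2)
        v2_inv_dense = np.linalg.inv(model.V12 - sb2 * (x1 @ x1.T))
        rel = np.abs(v2_inv_wb - v2_inv_dense).max() / np.abs(v2_inv_dense).max()
        worst = max(worst, float(rel))
    return CheckResult(
        "woodbury_downdate",
        worst < 1e-8,
        {"max_rel_diff": worst, "tolerance": 1e-8},
        n_instances,
    )


def check_variance_adjustment(seed: int, n_instances: int = 20) -> CheckResult:
    """(X1'V12⁻¹X1)⁻¹ − Iσβ² equals (X1'V2⁻¹X1)⁻¹; gap equals σβ²I."""
    worst_adj, worst_gap = 0.0, 0.0
    for n, p, p1, sb2, se2, s in _instance_grid(seed, n_instances):
        geno, pheno, part, vc = _simulated_instance(n, p, p1, sb2, se2, s)
        model = build_covariances(geno, part, vc)
        x1, _ = geno.split(part)
        v12_inv = spd_inverse(model.V12)
        adj = adjusted_variance(x1, v12_inv, sb2)
        oracle = np.linalg.inv(symmetrize(x1.T @ spd_inverse(model.V2) @ x1))
        worst_adj = max(worst_adj, float(np.abs(adj - oracle).max()))
        naive = np.linalg.inv(symmetrize(x1.T @ v12_inv @ x1))
        gap = naive - adj - sb2 * np.eye(p1)
        worst_gap = max(worst_gap, float(np.abs(gap).max()))
    return CheckResult(
        "variance_adjustment",
        worst_adj < 1e-8 and worst_gap < 1e-10,
        {
            "max_abs_diff_vs_v2": worst_adj,
            "tolerance_vs_v2": 1e-8,
            "max_abs_gap_error": worst_gap,
            "tolerance_gap": 1e-10,
        },
        n_instances,
    )


def check_blup_zero(seed: int, n_instances: int = 15) -> CheckResult:
    """Double-counted BLUP is zero; (α̂, β→2) match the reduced model.

    Uses the direct dense solve of the printed system, and cross-checks α̂
    against the GLS path and β→2 against the closed-form BLUP
    σβ²X2'V2⁻¹(y − X1α̂).
    """
    worst_b1, worst_red, worst_gls, worst_blup2 = 0.0, 0.0, 0.0, 0.0
    for n, p, p1, sb2, se2, s in _instance_grid(seed, n_instances):
        geno, pheno, part, vc = _simulated_instance(n, p, p1, sb2, se2, s)
        x1, x2 = geno.split(part)
        y = pheno.values
        system = build_mme(x1, x2, y, vc, treatment="scalar-iid")
        sol = solve_mme(system, method="direct")
        worst_b1 = max(worst_b1, float(np.abs(sol.blup1).max()))

        # reduced model: X1 excluded from the random part
        spec = EffectCovariance(
            B11=sb2 * np.eye(p1), B22=sb2 * np.eye(p - p1), R=se2 * np.eye(n)
        )
        a_red, b2_red = reduced_mme(x1, x2, y, spec)
        worst_red = max(
            worst_red,
            float(np.abs(sol.alpha_hat - a_red).max()),
            float(np.abs(sol.blup2 - b2_red).max()),
        )

        model = build_covariances(geno, part, vc)
        v12_inv = spd_inverse(model.V12)
        worst_gls = max(
            worst_gls,
            float(np.abs(sol.alpha_hat - gls_estimate(x1, v12_inv, y)).max()),
        )
        v2_inv = spd_inverse(model.V2)
        blup2_direct = sb2 * x2.T @ (v2_inv @ (y - x1 @ sol.alpha_hat))
        worst_blup2 = max(worst_blup2, float(np.abs(sol.blup2 - blup2_direct).max()))
    return CheckResult(
        "blup_zero",
        max(worst_b1, worst_red, worst_gls, worst_blup2) < 1e-8,
        {
            "max_abs_blup1": worst_b1,
            "max_abs_diff_reduced": worst_red,
            "max_abs_diff_gls": worst_gls,
            "max_abs_diff_blup2_formula": worst_blup2,
            "tolerance": 1e-8,
        },
        n_instances,
    )


def _paired_b12(p1: int, p2: int, var: float, rho: float) -> np.ndarray:
    """Cross-covariance pairing tested marker i with background marker i."""
    b12 = np.zeros((p1, p2))
    for i in range(min(p1, p2)):
        b12[i, i] = rho * var
    return b12


def check_correlated_blocks(seed: int, n_instances: int = 10, rho: float = 0.8) -> CheckResult:
    """β→1 = 0 when B12 = 0; β→1 + C·β→2 = 0 and α̂ shifts when B12 ≠ 0.

    C is the coupling block of the inverted prior metric (see mme module);
    the fixed-effect discrepancy between the correlated and independent
    treatments demonstrates the failure of the invariance property.
    """
    worst_indep, worst_coupling = 0.0, 0.0
    min_alpha_shift = np.inf
    for n, p, p1, sb2, se2, s in _instance_grid(seed, n_instances):
        p = min(p, 3 * n)  # keep the joint p×p precision inversion cheap
        b12 = _paired_b12(p1, p - p1, sb2, rho)
        cfg = SimulationConfig(
            n_samples=n,
            n_markers=p,
            sigma_beta2=sb2,
            sigma_e2=se2,
            fixed_alpha=0.5 * np.ones(p1),
            block_cov=EffectCovariance(
                B11=sb2 * np.eye(p1), B22=sb2 * np.eye(p - p1), B12=b12
            ),
            seed=s,
        )
        geno, pheno, _ = simulate_dataset(cfg, p1=p1)
        part = geno.partition(list(range(p1)))
        x1, x2 = geno.split(part)
        y = pheno.values
        r = se2 * np.eye(n)

        spec0 = EffectCovariance(
            B11=sb2 * np.eye(p1), B22=sb2 * np.eye(p - p1), R=r
        )
        sys0 = build_mme(x1, x2, y, spec0, treatment="block-independent")
        sol0 = solve_mme(sys0, method="direct")
        worst_indep = max(worst_indep, float(np.abs(sol0.blup1).max()))

        spec1 = EffectCovariance(
            B11=sb2 * np.eye(p1), B22=sb2 * np.eye(p - p1), B12=b12, R=r
        )
        sys1 = build_mme(x1, x2, y, spec1, treatment="block-correlated")
        sol1 = solve_mme_correlated(sys1, method="direct")
        worst_coupling = max(
            worst_coupling,
            float(np.abs(sol1.blup1 + sol1.coupling @ sol1.blup2).max()),
        )
        min_alpha_shift = min(
            min_alpha_shift,
            float(np.abs(sol1.alpha_hat - sol0.alpha_hat).max()),
        )
    return CheckResult(
        "correlated_blocks",
        worst_indep < 1e-8 and worst_coupling < 1e-8 and min_alpha_shift > 1e-4,
        {
            "max_abs_blup1_independent": worst_indep,
            "max_abs_coupling_identity": worst_coupling,
            "tolerance": 1e-8,
            "min_alpha_shift": min_alpha_shift,
            "alpha_shift_floor": 1e-4,
            "rho": rho,
        },
        n_instances,
    )


def check_conditional_model(seed: int, n_instances: int = 10) -> CheckResult:
    """Schur complement, signal decomposition and exact-residual BLUP(δ) = 0."""
    worst_schur, worst_decomp, worst_delta = 0.0, 0.0, 0.0
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(10, 40))
        p1 = int(rng.integers(1, 4))
        p2 = int(rng.integers(p1 + 1, 12))
        # random PD joint covariance via a Wishart-style construction
        a = rng.standard_normal((p1 + p2, p1 + p2 + 2))
        joint = a @ a.T / (p1 + p2 + 2) + 0.1 * np.eye(p1 + p2)
        b = EffectCovariance(
            B11=joint[:p1, :p1],
            B22=joint[p1:, p1:],
            B12=joint[:p1, p1:],
            R=np.eye(n),
        )
        x1 = rng.standard_normal((n, p1))
        x2 = rng.standard_normal((n, p2))
        x1_star, b21dot = conditional_design(x1, x2, b)

        schur_oracle = b.B22 - b.B21 @ np.linalg.inv(b.B11) @ b.B12
        worst_schur = max(worst_schur, float(np.abs(b21dot - schur_oracle).max()))

        beta1 = rng.standard_normal(p1)
        gamma = b.B21 @ np.linalg.inv(b.B11)
        decomp = (x1 @ beta1 + x2 @ (gamma @ beta1)) - x1_star @ beta1
        worst_decomp = max(worst_decomp, float(np.abs(decomp).max()))

        # y generated exactly as X1* beta1 -> zero residual -> BLUP(delta) = 0
        y = x1_star @ beta1
        v2s = symmetrize(x2 @ b21dot @ x2.T + b.R)
        v2s_inv = spd_inverse(v2s)
        beta1_est = conditional_gls(x1_star, x2, b21dot, b.R, y)
        delta = conditional_blup_delta(x2, b21dot, v2s_inv, y, x1_star, beta1_est)
        worst_delta = max(worst_delta, float(np.abs(delta).max()))
    return CheckResult(
        "conditional_model",
        worst_schur < 1e-10 and worst_decomp < 1e-12 and worst_delta < 1e-8,
        {
            "max_abs_schur_diff": worst_schur,
            "tolerance_schur": 1e-10,
            "max_abs_decomposition_diff": worst_decomp,
            "tolerance_decomposition": 1e-12,
            "max_abs_blup_delta_exact_fit": worst_delta,
            "tolerance_delta": 1e-8,
        },
        n_instances,
    )


def check_calibration(
    seed: int,
    n_replicates: int = 2000,
    n: int = 100,
    p: int = 200,
    alpha_level: float = 0.05,
) -> CheckResult:
    """Type-I error of the Wald test under the null at nominal 5%.

    The tested marker carries no fixed effect and is excluded from the
    generative random effects; each replicate simulates fresh genotypes,
    background effects and residuals, estimates the tested effect under V2
    and tests with the adjusted and the naive variance. The adjusted
    rejection rate should fall in the 99% binomial interval around the
    nominal level; the naive rate should not exceed the adjusted one
    (the naive variance overstates uncertainty).
    """
    rng = np.random.default_rng(seed)
    from scipy import stats

    rej_adj = 0
    rej_naive = 0
    crit = stats.chi2.ppf(1 - alpha_level, df=1)
    for _ in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = SimulationConfig(
            n_samples=n, n_markers=p, sigma_beta2=1.0, sigma_e2=1.0, seed=s
        )
        geno, pheno, truth = simulate_dataset(cfg, p1=1)
        # null: remove the tested marker's random-effect contribution
        x1 = geno.codes[:, :1]
        x2 = geno.codes[:, 1:]
        y = pheno.values - x1.ravel() * truth["beta1"][0]
        part = geno.partition([0])
        vc = VarianceComponents(1.0, 1.0)
        model = build_covariances(geno, part, vc)
        v2_inv = model.v2_inverse()
        est = gls_estimate(x1, v2_inv, y)
        var_adj = 1.0 / (x1.T @ v2_inv @ x1).item()
        stat_adj = float(est[0] ** 2 / var_adj)
        stat_naive = float(est[0] ** 2 / (var_adj + vc.sigma_beta2))
        rej_adj += stat_adj > crit
        rej_naive += stat_naive > crit
    rate_adj = rej_adj / n_replicates
    rate_naive = rej_naive / n_replicates
    half = 2.576 * np.sqrt(alpha_level * (1 - alpha_level) / n_replicates)
    lo, hi = alpha_level - half, alpha_level + half
    return CheckResult(
        "calibration",
        (lo <= rate_adj <= hi) and (rate_naive <= rate_adj),
        {
            "rejection_rate_adjusted": rate_adj,
            "rejection_rate_naive": rate_naive,
            "binomial_99_interval": (lo, hi),
            "nominal_level": alpha_level,
        },
        n_replicates,
    )


def check_scan_equivalence(
    seed: int, n: int = 80, p: int = 300, n_sets: int = 300
) -> CheckResult:
    """Full singleton scans under both strategies produce identical rows."""
    cfg = SimulationConfig(
        n_samples=n, n_markers=p, sigma_beta2=1.0, sigma_e2=1.0, seed=seed
    )
    geno, pheno, _ = simulate_dataset(cfg, p1=1)
    sets = [[m] for m in geno.marker_ids[:n_sets]]
    base = dict(set_definitions=sets, sigma_beta2=1.0, sigma_e2=1.0)
    t_reuse = run_scan(geno, pheno, ScanConfig(strategy="reuse-v12", **base))
    t_perset = run_scan(geno, pheno, ScanConfig(strategy="per-set-v2", **base))
    worst = 0.0
    for col in ("estimate", "se_adjusted", "se_naive"):
        a = t_reuse[col].map(float).to_numpy()
        b = t_perset[col].map(float).to_numpy()
        worst = max(worst, float(np.abs(a - b).max()))
    return CheckResult(
        "scan_equivalence",
        worst < 1e-8,
        {"max_abs_diff": worst, "tolerance": 1e-8, "n_sets": len(sets)},
        len(sets),
    )


def run_all_checks(seed: int = 1, fast: bool = False) -> list[CheckResult]:
    """Run the whole battery; ``fast`` shrinks instance/replicate counts."""
    k = 5 if fast else None
    return [
        check_blue_invariance(seed, n_instances=k or 50),
        check_woodbury(seed + 1, n_instances=k or 20),
        check_variance_adjustment(seed + 2, n_instances=k or 20),
        check_blup_zero(seed + 3, n_instances=k or 15),
        check_correlated_blocks(seed + 4, n_instances=k or 10),
        check_conditional_model(seed + 5, n_instances=k or 10),
        check_calibration(seed + 6, n_replicates=200 if fast else 2000),
        check_scan_equivalence(
            seed + 7,
            n=40 if fast else 80,
            p=80 if fast else 300,
            n_sets=40 if fast else 300,
        ),
    ]


def format_check_table(results: list[CheckResult]) -> str:
    lines = [f"{'check':24s} {'status':6s} metrics"]
    for r in results:
        metrics = ", ".join(
            f"{k}={v:.3e}" if isinstance(v, float) else f"{k}={v}"
            for k, v in r.metrics.items()
        )
        lines.append(f"{r.name:24s} {'PASS' if r.passed else 'FAIL':6s} {metrics}")
    return "\n".join(lines)
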