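"""Calibration experiments run by the analysis drivers and acceptance checks.

These stand where the study's accession-only quantities cannot be recomputed
from packaged data: they measure, on synthetic data of known truth, that the
estimators implemented here behave as the theory says they must.
"""

from __future__ import annotations

import numpy as np

from .dec import DECModelSpec, fit_dec
from .distances import pairwise_counts, tn93_gamma_distance
from .likelihood import SubstitutionModel
from .simulate import sim_dec_history, sim_sequences, sim_tree
from .trees import read_newick

#: cyt b-like simulation model: empirical-looking base composition, strong
#: transition bias, gamma shape matching the distance correction in use.
CYTB_LIKE = dict(
    freqs=np.array([0.31, 0.27, 0.12, 0.30]),
    kappa1=4.0,
    kappa2=8.0,
)


def tn93_consistency(
    t: float = 0.05,
    length: int = 100_000,
    reps: int = 50,
    alpha: float = 1.4964,
    seed: int = 0,
) -> dict:
    """Consistency of the gamma-corrected TN93 distance estimator.

    Simulates two sequences separated by total path length ``2 t`` under
    TN93+G (shape ``alpha``) and compares the mean estimated distance with
    the truth; also returns the Monte-Carlo standard error of the mean.
    """
    # 64 categories: near-continuous gamma, matching the estimator's
    # continuous-rates assumption
    model = SubstitutionModel(alpha=alpha, n_categories=64, **CYTB_LIKE)
    tree = read_newick(f"(x:{t},y:{t});")
    estimates = []
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        a = sim_sequences(tree, model, length=length,
                          seed=int(rng.integers(2 ** 31)))
        counts = pairwise_counts(a, 0, 1)
        estimates.append(tn93_gamma_distance(counts, alpha))
    estimates = np.asarray(estimates)
    return {
        "true_distance": 2 * t,
        "mean_estimate": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(reps)),
        "reps": reps,
        "length": length,
    }


def dec_parameter_recovery(
    n_replicates: int = 20,
    n_tips: int = 100,
    d: float = 0.03,
    e: float = 0.005,
    n_areas: int = 4,
    root_age: float = 10.0,
    seed: int = 0,
) -> dict:
    """Dispersal-rate recovery on simulated DEC histories.

    Each replicate simulates a Yule chronogram, a DEC range history under
    the true (d, e) on an unconstrained ``n_areas``-area model, and refits
    by maximum likelihood.  Reports the median estimates and the median
    ratio d_hat / d.
    """
    areas = tuple(chr(65 + i) for i in range(n_areas))
    spec = DECModelSpec.m0(areas=areas)
    rng = np.random.default_rng(seed)
    d_hats, e_hats = [], []
    for rep in range(n_replicates):
        s = int(rng.integers(2 ** 31))
        tree = sim_tree(n_tips, root_age=root_age, seed=s)
        tips, _, _ = sim_dec_history(tree, spec, d=d, e=e, seed=s + 1)
        fit = fit_dec(tree, tips, spec, seed=s + 2, n_restarts=1)
        d_hats.append(fit.d)
        e_hats.append(fit.e)
    d_hats = np.asarray(d_hats)
    return {
        "true_d": d,
        "true_e": e,
        "median_d_hat": float(np.median(d_hats)),
        "median_e_hat": float(np.median(e_hats)),
        "median_d_ratio": float(np.median(d_hats) / d),
        "n_replicates": n_replicates,
        "n_tips": n_tips,
    }


def landmark_displacement_recovery(
    n_landmarks: int = 15,
    n_per_group: int = 15,
    displacement: float = 0.12,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict:
    """Recovery of a planted between-group shape displacement.

    Two groups differ by a fixed displacement applied to the first third of
    the landmarks; after GPA + relative warps, the between-group separation
    re-expressed in the original shape space is compared with the planted
    displacement magnitude.
    """
    from .shape import gpa, relative_warps
    from .simulate import sim_landmarks

    rng = np.random.default_rng(seed)
    mean = rng.normal(0, 1.0, size=(n_landmarks, 2))
    mean = mean - mean.mean(axis=0)
    mean = mean / np.sqrt((mean ** 2).sum())
    disp = np.zeros((n_landmarks, 2))
    disp[: n_landmarks // 3, 0] = displacement
    # project into the shape tangent space: superimposition removes net
    # translation, scale (component along the mean) and rotation (component
    # along the 90-degree-rotated mean), so only the residual is recoverable
    disp -= disp.mean(axis=0)
    rot_mean = np.stack([-mean[:, 1], mean[:, 0]], axis=1)
    for basis in (mean, rot_mean / np.sqrt((rot_mean ** 2).sum())):
        disp -= (disp * basis).sum() * basis
    configs = sim_landmarks(
        mean, {"A": n_per_group, "B": n_per_group}, {"B": disp},
        noise_sd=noise_sd, seed=seed,
    )
    aligned = gpa(configs)
    warps = relative_warps(aligned)
    groups = np.array([str(lab[0]).split("_")[0] for lab in warps.labels])
    mean_a = aligned.coords[groups == "A"].mean(axis=0)
    mean_b = aligned.coords[groups == "B"].mean(axis=0)
    recovered = float(np.sqrt(((mean_b - mean_a) ** 2).sum()))
    planted = float(np.sqrt((disp ** 2).sum()))
    sep = np.abs(
        warps.scores[groups == "A", 0].mean()
        - warps.scores[groups == "B", 0].mean()
    )
    return {
        "planted_magnitude": planted,
        "recovered_magnitude": recovered,
        "relative_error": abs(recovered - planted) / planted,
        "rw1_group_separation": float(sep),
        "rw1_variance_fraction": float(warps.variance_fractions[0]),
    }
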