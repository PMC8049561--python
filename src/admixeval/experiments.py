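"""Figure-level experiments: simulation studies of the admixture statistic.

Every experiment simulates its own data through :mod:`admixeval.demography`
(optionally corrupted through :mod:`admixeval.degrade`), runs the model fits
of :mod:`admixeval.qpadm`/:mod:`admixeval.search`, and returns plain tables.
Two closed-form computations live here as well: the constrained binomial
likelihood-ratio demonstration (a coin-flipping analogy for how plausibility
P-values are used) and the expected number of sites surviving the
all-population intersection under random missingness.

Experiments run at a configurable genome ``scale`` (multiplier on the 22
human autosome lengths).  At reduced scale the jackknife block size is
shrunk with the genome, with a floor of 2e-3 Morgans below which blocks
become comparable to the correlation length of the genealogy and standard
errors degrade.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from admixeval.degrade import DegradeConfig, apply_degradation
from admixeval.demography import (
    STANDARD_REFERENCES,
    STANDARD_SOURCES,
    STANDARD_TARGET,
    DemographyScenario,
    SimulationConfig,
    build_continuous_after_pulse,
    build_many_pops_tree,
    build_reference_geneflow_tree,
    build_standard_tree,
    build_stepping_stone,
    simulate_genotypes,
)
from admixeval.fstats import F4Workspace, _pseudovalues
from admixeval.genotype import GenotypeMatrix, pairwise_fst, pca_projection
from admixeval.qpadm import QpAdmModel, QpAdmOptions, clade_test, fit_rank, qpadm
from admixeval.search import (
    ProtocolKind,
    SearchProtocol,
    enumerate_models,
    evaluate_models,
    pvalue_ranking_frequency,
    pvalue_uniformity,
)

#: Below this block size (Morgans) jackknife blocks approach the correlation
#: length of the genealogy and the variance estimate degrades (chosen by a
#: pilot block-size sweep; at 1e-3 the rank-test P-values skew low).
MIN_BLOCK_SIZE = 2e-3

#: The six source pairs whose P-value distributions are contrasted under the
#: base reference set (the optimal pair first).
SIX_MODEL_SOURCES = [("5", "9"), ("4", "9"), ("3", "9"), ("2", "9"), ("1", "9"), ("11", "9")]

#: Populations needed by the standard model alone (cheaper simulations).
STANDARD_MODEL_POPS = ("14", "5", "9", "0", "7", "10", "12", "13")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def binom_lrt_pvalue(n_flips: int, n_heads: int, lower: float, upper: float) -> float:
    """P-value of the constrained binomial likelihood-ratio test.

    Tests H0: lower < p <= upper against the unconstrained alternative for
    ``n_heads`` successes in ``n_flips`` trials.  If the MLE lies inside the
    bin the likelihood ratio is 1 and P = 1; otherwise the constrained
    supremum is evaluated at the nearest bin endpoint and ``-2 log LR`` is
    referred to a chi-squared distribution with 1 df.
    """
    if not 0 <= n_heads <= n_flips or n_flips <= 0:
        raise ValueError("need 0 <= n_heads <= n_flips")
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError("need 0 <= lower < upper <= 1")
    p_hat = n_heads / n_flips

    def loglik(p: float) -> float:
        if p in (0.0, 1.0):
            p = min(max(p, 1e-300), 1 - 1e-16)
        return n_heads * np.log(p) + (n_flips - n_heads) * np.log1p(-p)

    if lower < p_hat <= upper or (lower == 0.0 and p_hat == 0.0):
        return 1.0
    p0 = upper if p_hat > upper else lower
    stat = 2.0 * (loglik(p_hat) - loglik(p0))
    return float(stats.chi2.sf(stat, df=1))


COIN_BINS = [(i / 10, (i + 1) / 10) for i in range(10)]


def coin_demo() -> pd.DataFrame:
    """The full grid of constrained-binomial P-values for 64/100 and
    646/1000 heads over the ten width-0.1 bins."""
    rows = []
    for n, h in ((100, 64), (1000, 646)):
        for lo, hi in COIN_BINS:
            rows.append({
                "n_flips": n, "n_heads": h, "lower": lo, "upper": hi,
                "p_value": binom_lrt_pvalue(n, h, lo if lo > 0 else 0.0, hi),
            })
    return pd.DataFrame(rows)


def expected_intersection_snps(
    total_sites: float, missing_rate: float, inds_per_pop: int, n_pops: int
) -> float:
    """Expected number of sites at which every population retains data.

    Under i.i.d. per-individual missingness at ``missing_rate``, a site
    survives the all-population intersection iff each of the ``n_pops``
    populations keeps at least one of its ``inds_per_pop`` individuals:
    ``total_sites * (1 - rate^inds)^pops``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing rate must be in [0, 1]")
    if inds_per_pop < 1 or n_pops < 1:
        raise ValueError("need at least one individual and one population")
    return float(total_sites * (1.0 - missing_rate**inds_per_pop) ** n_pops)


# ---------------------------------------------------------------------------
# shared simulation helpers
# ---------------------------------------------------------------------------

def scaled_block_size(scale: float) -> float:
    """Jackknife block size used at a given genome scale (floor 2e-3 M)."""
    from admixeval.fstats import DEFAULT_BLOCK_SIZE

    return max(DEFAULT_BLOCK_SIZE * scale, MIN_BLOCK_SIZE)


def derive_seeds(master_seed: int, tag: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(tag)])
    return ss.generate_state(n) % (2**31 - 2) + 1


def simulate_standard(
    alpha: float, scale: float, seed: int,
    samples: int | dict[str, int] = 10,
    scenario: DemographyScenario | None = None,
) -> GenotypeMatrix:
    config = SimulationConfig(scale=scale, seed=int(seed), samples_per_population=samples)
    return simulate_genotypes(scenario or build_standard_tree(alpha), config)


def standard_model(references=STANDARD_REFERENCES) -> QpAdmModel:
    return QpAdmModel(
        target=STANDARD_TARGET,
        sources=list(STANDARD_SOURCES),
        references=list(references),
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def pvalue_dist(
    replicates: int = 200,
    scale: float = 1 / 400,
    seed: int = 1,
    drop_reference_0: bool = False,
    degrade: DegradeConfig | None = None,
) -> dict:
    """P-value distributions of the six competing source-pair models.

    Simulates ``replicates`` standard datasets (alpha = 0.5) and fits the
    six models pairing source 9 with populations 5, 4, 3, 2, 1 and 11 under
    the base reference set (optionally with reference 0 removed).  Returns
    per-replicate fits, per-model KS uniformity tests, and the fraction of
    replicates in which the optimal pair attains the highest P-value.
    """
    refs = [r for r in STANDARD_REFERENCES if not (drop_reference_0 and r == "0")]
    models = [QpAdmModel(STANDARD_TARGET, list(srcs), refs) for srcs in SIX_MODEL_SOURCES]
    options = QpAdmOptions(block_size=scaled_block_size(scale), weight_se=False)
    pops = sorted({p for m in models for p in m.all_populations}, key=int)
    seeds = derive_seeds(seed, 20, replicates)

    fits = []
    for i in range(replicates):
        G = simulate_standard(0.5, scale, seeds[i], samples={p: 10 for p in pops})
        if degrade is not None:
            G = apply_degradation(G, degrade, int(seeds[i]) + 1)
        ws = F4Workspace(G, populations=pops, block_size=options.block_size)
        fits.append([qpadm(ws, m, options) for m in models])

    table = pd.DataFrame([
        {"replicate": i, "sources": "+".join(m.sources), "p_value": f.p_value,
         "plausible": f.plausible, "alpha_hat": f.weights[0]}
        for i, row in enumerate(fits) for m, f in zip(models, row)
    ])
    ks = {}
    if replicates >= 20:
        for j, m in enumerate(models):
            ps = [fits[i][j].p_value for i in range(replicates)]
            ks["+".join(m.sources)] = pvalue_uniformity(ps)
    return {
        "fits": fits,
        "models": models,
        "table": table,
        "ks": ks,
        "optimal_highest_p_fraction": pvalue_ranking_frequency(fits, 0),
    }


def alpha_accuracy(
    alphas: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 1)),
    replicates: int = 20,
    scale: float = 1 / 400,
    seed: int = 1,
    degrade: DegradeConfig | None = None,
) -> pd.DataFrame:
    """Admixture-proportion calibration across the alpha grid.

    For each simulated alpha, fits the standard model on ``replicates``
    independent datasets and records the estimate, its jackknife SE, and
    whether the truth lies within 3 SEs.
    """
    model = standard_model()
    options = QpAdmOptions(block_size=scaled_block_size(scale))
    samples = {p: 10 for p in STANDARD_MODEL_POPS}
    rows = []
    for a_idx, alpha in enumerate(alphas):
        seeds = derive_seeds(seed, 30 + a_idx, replicates)
        for i in range(replicates):
            G = simulate_standard(alpha, scale, seeds[i], samples=samples)
            if degrade is not None:
                G = apply_degradation(G, degrade, int(seeds[i]) + 1)
            fit = qpadm(G, model, options)
            rows.append({
                "alpha": alpha, "replicate": i,
                "alpha_hat": fit.weights[0], "se": fit.weight_ses[0],
                "p_value": fit.p_value,
                "covered": abs(fit.weights[0] - alpha) <= 3 * fit.weight_ses[0],
            })
    return pd.DataFrame(rows)


def rotating_candidates(target: str = STANDARD_TARGET, include_6: bool = False) -> list[str]:
    """Default rotating candidate pool: every population except the target
    (and except population 6, a clade-mate of source 5, unless requested)."""
    pool = [str(i) for i in range(16) if str(i) != target]
    if not include_6:
        pool = [p for p in pool if p != "6"]
    return pool


def model_comparison(
    replicates: int = 20,
    scale: float = 1 / 400,
    seed: int = 1,
    protocols: tuple[str, ...] = ("base", "rotating"),
    exclude_sources: tuple[str, ...] = (),
    degrade: DegradeConfig | None = None,
    k: int = 2,
) -> dict[str, pd.DataFrame]:
    """Base-vs-rotating source-pair comparison on shared replicates.

    The base protocol draws source pairs from the populations outside the
    fixed reference set; the rotating protocol draws the same pairs from the
    full candidate pool, rotating non-sources into the references.
    """
    base_cands = [p for p in rotating_candidates() if p not in STANDARD_REFERENCES
                  and p not in exclude_sources]
    rot_cands = [p for p in rotating_candidates() if p not in exclude_sources]
    protos = {
        "base": SearchProtocol(ProtocolKind.BASE, base_cands, k=k,
                               base_references=list(STANDARD_REFERENCES)),
        "rotating": SearchProtocol(ProtocolKind.ROTATING, rot_cands, k=k),
    }
    options = QpAdmOptions(block_size=scaled_block_size(scale), weight_se=False)
    seeds = derive_seeds(seed, 40, replicates)
    workspaces = []
    for i in range(replicates):
        G = simulate_standard(0.5, scale, seeds[i])
        if degrade is not None:
            G = apply_degradation(G, degrade, int(seeds[i]) + 1)
        workspaces.append(F4Workspace(G, block_size=options.block_size))
    out = {}
    for name in protocols:
        models = enumerate_models(protos[name], STANDARD_TARGET)
        out[name] = evaluate_models(workspaces, models, options)
    return out


def clade_scan(
    target: str,
    replicates: int = 20,
    scale: float = 1 / 150,
    seed: int = 1,
    sources: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Single-source (clade) models under the rotating protocol.

    For each candidate source, the references are all remaining candidates;
    records the P-value per replicate and source.
    """
    cands = [p for p in [str(i) for i in range(16)] if p != target]
    if target != "6":
        cands = [p for p in cands if p != "6"]
    sources = tuple(sources) if sources is not None else tuple(cands)
    options = QpAdmOptions(block_size=scaled_block_size(scale), weight_se=False)
    seeds = derive_seeds(seed, 50, replicates)
    rows = []
    for i in range(replicates):
        G = simulate_standard(0.5, scale, seeds[i])
        ws = F4Workspace(G, block_size=options.block_size)
        for src in sources:
            refs = [c for c in cands if c != src]
            fit = clade_test(ws, target, src, refs, options)
            rows.append({"replicate": i, "target": target, "source": src,
                         "p_value": fit.p_value, "plausible": fit.plausible})
    return pd.DataFrame(rows)


def jackknife_sweep(
    block_sizes: tuple[float, ...] = (2e-5, 2e-4, 1e-3, 5e-3, 2e-2),
    replicates: int = 10,
    scale: float = 1 / 400,
    seed: int = 1,
) -> pd.DataFrame:
    """Standard-model fits across jackknife block sizes on shared data."""
    model = standard_model()
    samples = {p: 10 for p in STANDARD_MODEL_POPS}
    seeds = derive_seeds(seed, 60, replicates)
    rows = []
    for i in range(replicates):
        G = simulate_standard(0.5, scale, seeds[i], samples=samples)
        for bs in block_sizes:
            fit = qpadm(G, model, QpAdmOptions(block_size=bs))
            rows.append({
                "replicate": i, "block_size": bs, "alpha_hat": fit.weights[0],
                "se": fit.weight_ses[0], "p_value": fit.p_value,
                "n_blocks": fit.f4.block_counts.shape[1],
            })
    return pd.DataFrame(rows)


def reference_geneflow(
    gammas: tuple[float, ...] = (0.01, 0.05, 0.10, 0.25),
    pulse_generations: tuple[float, ...] = (200.0, 350.0),
    alpha: float = 0.5,
    replicates: int = 6,
    scale: float = 1 / 400,
    seed: int = 1,
    donor: str = "10",
    recipient: str = "9",
) -> pd.DataFrame:
    """Bias of the admixture estimate under reference-to-source gene flow.

    A pulse of proportion gamma from ``donor`` into ``recipient`` is added at
    generation 200 (after the recipient's split from the 14b donor lineage —
    a model violation) or 350 (before it — harmless), and the standard model
    is fit.
    """
    options = QpAdmOptions(block_size=scaled_block_size(scale))
    samples = {p: 10 for p in STANDARD_MODEL_POPS}
    rows = []
    tag = 70
    for t in pulse_generations:
        for gamma in gammas:
            scenario = build_reference_geneflow_tree(alpha, gamma, t, donor, recipient)
            seeds = derive_seeds(seed, tag, replicates)
            tag += 1
            for i in range(replicates):
                G = simulate_standard(alpha, scale, seeds[i], samples=samples,
                                      scenario=scenario)
                fit = qpadm(G, standard_model(), options)
                rows.append({
                    "pulse_generation": t, "gamma": gamma, "alpha": alpha,
                    "replicate": i, "alpha_hat": fit.weights[0],
                    "se": fit.weight_ses[0], "p_value": fit.p_value,
                })
    return pd.DataFrame(rows)


def many_refs(
    replicates: int = 10,
    n_added: int = 108,
    scale: float = 1 / 250,
    seed: int = 1,
    samples_added: int = 3,
) -> pd.DataFrame:
    """P-value trajectories as reference populations are piled onto a true
    model.

    Simulates the 118-population scenario, fits the standard model, then
    adds the remaining populations one at a time (seeded random order) to
    the reference set, re-evaluating the rank test at each step.  Records
    the P-value per (replicate, number of added references).
    """
    scenario = build_many_pops_tree()
    core = {str(i): 10 for i in range(16)}
    added_labels = [lab for lab in scenario.labels.values() if int(lab) >= 16]
    samples = dict(core, **{lab: samples_added for lab in added_labels})
    block_size = scaled_block_size(scale)
    pool = [p for p in ([str(i) for i in range(16)] + added_labels)
            if p not in ("14", "5", "9", "6", *STANDARD_REFERENCES)]
    seeds = derive_seeds(seed, 80, replicates)
    rows = []
    for i in range(replicates):
        rng = np.random.default_rng(int(seeds[i]))
        order = list(rng.permutation(pool))[:n_added]
        refs_full = list(STANDARD_REFERENCES) + order
        G = simulate_standard(0.5, scale, seeds[i], samples=samples, scenario=scenario)
        ws = F4Workspace(G, populations=["14", "5", "9"] + refs_full, block_size=block_size)

        # all design quadruples at the maximal reference set, row-major
        quads = [("14", s, refs_full[0], rj) for s in ("5", "9") for rj in refs_full[1:]]
        nb = ws.blocks.n_blocks
        sums = np.empty((len(quads), nb))
        counts = np.empty((len(quads), nb))
        for qi, (a, b, c, dd) in enumerate(quads):
            sums[qi], counts[qi] = ws.f4_block_sums(a, b, c, dd)
        tot_s, tot_n = sums.sum(axis=1), counts.sum(axis=1)
        theta = tot_s / tot_n
        taus = np.empty_like(sums)
        for qi in range(len(quads)):
            taus[qi], _ = _pseudovalues(theta[qi], tot_s[qi], tot_n[qi],
                                        sums[qi], counts[qi])
        n_nonempty = (counts > 0).sum(axis=1).astype(float)
        taus_scaled = taus / np.sqrt(n_nonempty)[:, None]

        n_cols_full = len(refs_full) - 1
        for extra in range(0, n_added + 1):
            ncols = 4 + extra
            idx = np.concatenate([np.arange(ncols), n_cols_full + np.arange(ncols)])
            C = taus_scaled[idx] @ taus_scaled[idx].T
            C = 0.5 * (C + C.T)
            X = theta[idx].reshape(2, ncols)
            _, stat, _ = fit_rank(X, C, 1)
            df = (5 + extra) - 2
            rows.append({
                "replicate": i, "n_added": extra, "n_references": 5 + extra,
                "statistic": stat, "df": df,
                "p_value": float(stats.chi2.sf(stat, df)),
            })
    return pd.DataFrame(rows)


def continuous_after_pulse(
    alphas: tuple[float, ...] = (0.0, 0.5),
    migration_rates: tuple[float, ...] = (0.0, 1e-5, 1e-4, 1e-3, 1e-2),
    replicates: int = 5,
    scale: float = 1 / 400,
    seed: int = 1,
) -> pd.DataFrame:
    """Estimates when a pulse at generation 240 is followed by continuous
    gene flow from both sources into the target."""
    options = QpAdmOptions(block_size=scaled_block_size(scale))
    samples = {p: 10 for p in STANDARD_MODEL_POPS}
    rows = []
    tag = 90
    for alpha in alphas:
        for m in migration_rates:
            scenario = build_continuous_after_pulse(alpha, m)
            seeds = derive_seeds(seed, tag, replicates)
            tag += 1
            for i in range(replicates):
                G = simulate_standard(alpha, scale, seeds[i], samples=samples,
                                      scenario=scenario)
                fit = qpadm(G, standard_model(), options)
                rows.append({
                    "alpha": alpha, "m": m, "replicate": i,
                    "alpha_hat": fit.weights[0], "se": fit.weight_ses[0],
                    "p_value": fit.p_value,
                })
    return pd.DataFrame(rows)


STEPPING_REFERENCES = ("0", "4", "6", "7", "8")


def stepping_stone(
    migration_rates: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
    replicates: int = 20,
    scale: float = 1 / 50,
    seed: int = 1,
    with_summaries: bool = False,
    extreme_target: bool = False,
) -> dict:
    """Admixture models fitted to a migration cline.

    Deme 2 is modeled as a two-way mixture of its chain neighbours 1 and 3
    with demes 0 and 4 and the three outgroups as references.  With
    ``extreme_target=True`` deme 1 is additionally modeled from sources 2 and
    3 (both on the same side of it along the cline), the case where the
    estimated weight escapes [0, 1].
    """
    options = QpAdmOptions(block_size=scaled_block_size(scale))
    results = []
    extreme_rows = []
    fst_frames = {}
    pca_frame = None
    tag = 110
    for m in migration_rates:
        scenario = build_stepping_stone(m)
        seeds = derive_seeds(seed, tag, replicates)
        tag += 1
        for i in range(replicates):
            G = simulate_standard(0.5, scale, seeds[i], scenario=scenario)
            ws = F4Workspace(G, block_size=options.block_size)
            fit = qpadm(ws, QpAdmModel("2", ["1", "3"], list(STEPPING_REFERENCES)), options)
            results.append({
                "m": m, "replicate": i, "p_value": fit.p_value,
                "plausible": fit.plausible, "w1": fit.weights[0], "w3": fit.weights[1],
                "se1": fit.weight_ses[0],
            })
            if extreme_target:
                efit = qpadm(ws, QpAdmModel("1", ["2", "3"],
                                            ["0", "4", "5", "6", "7", "8"]), options)
                extreme_rows.append({
                    "m": m, "replicate": i, "alpha_hat": efit.weights[0],
                    "se": efit.weight_ses[0], "p_value": efit.p_value,
                })
            if with_summaries and i == 0:
                demes = [str(j) for j in range(6)]
                fst = pd.DataFrame(
                    [[pairwise_fst(G, a, b) if a != b else 0.0 for b in demes]
                     for a in demes], index=demes, columns=demes)
                fst_frames[m] = fst
                pca_frame = pca_projection(G, demes)
    out = {"fits": pd.DataFrame(results)}
    if extreme_target:
        out["extreme"] = pd.DataFrame(extreme_rows)
    if with_summaries:
        out["fst"] = fst_frames
        out["pca"] = pca_frame
    return out


def allsnps_comparison(
    missing_rates: tuple[float, ...] = (0.25, 0.9),
    replicates: int = 3,
    scale: float = 1 / 400,
    seed: int = 1,
) -> pd.DataFrame:
    """Standard-model fits under both site policies at high missingness."""
    model = standard_model()
    samples = {p: 10 for p in STANDARD_MODEL_POPS}
    rows = []
    tag = 130
    for rate in missing_rates:
        seeds = derive_seeds(seed, tag, replicates)
        tag += 1
        for i in range(replicates):
            G = simulate_standard(0.5, scale, seeds[i], samples=samples)
            G = apply_degradation(G, DegradeConfig(missing_rate=rate), int(seeds[i]) + 1)
            for allsnps in (True, False):
                options = QpAdmOptions(allsnps=allsnps,
                                       block_size=scaled_block_size(scale))
                fit = qpadm(G, model, options)
                rows.append({
                    "missing_rate": rate, "replicate": i, "allsnps": allsnps,
                    "alpha_hat": fit.weights[0], "se": fit.weight_ses[0],
                    "p_value": fit.p_value, "n_snps_used": fit.n_snps_used,
                })
    return pd.DataFrame(rows)


def combined_degradation(
    alphas: tuple[float, ...] = (0.1, 0.5, 0.9),
    missing_rates: tuple[float, ...] = (0.25, 0.75),
    sample_sizes: tuple[int, ...] = (10, 2, 1),
    damage_scopes: tuple[str, ...] = ("target", "all"),
    replicates: int = 3,
    scale: float = 1 / 400,
    seed: int = 1,
) -> pd.DataFrame:
    """Stacked corruption (damage + pseudohaploid + missingness + sample
    size); variance of the estimate grows with each factor."""
    model = standard_model()
    options = QpAdmOptions(block_size=scaled_block_size(scale))
    samples = {p: 10 for p in STANDARD_MODEL_POPS}
    rows = []
    tag = 140
    for alpha in alphas:
        seeds = derive_seeds(seed, tag, replicates)
        tag += 1
        for i in range(replicates):
            G0 = simulate_standard(alpha, scale, seeds[i], samples=samples)
            for miss in missing_rates:
                for n_per_pop in sample_sizes:
                    for scope in damage_scopes:
                        damage_pops = (["14"] if scope == "target"
                                       else list(STANDARD_MODEL_POPS))
                        cfg = DegradeConfig(
                            damage_rate=0.05, damage_populations=damage_pops,
                            pseudohaploid=True, missing_rate=miss,
                            sample_sizes={p: n_per_pop for p in STANDARD_MODEL_POPS},
                        )
                        G = apply_degradation(G0, cfg, int(seeds[i]) + 1)
                        fit = qpadm(G, model, options)
                        rows.append({
                            "alpha": alpha, "missing": miss, "n_per_pop": n_per_pop,
                            "damage_scope": scope, "replicate": i,
                            "alpha_hat": fit.weights[0], "p_value": fit.p_value,
                            "in_range": bool(0 <= fit.weights[0] <= 1),
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

EXPERIMENTS = {
    "coin_demo": lambda spec: coin_demo(),
    "pvalue_dist": lambda spec: pvalue_dist(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    )["table"],
    "jackknife_sweep": lambda spec: jackknife_sweep(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "alpha_accuracy": lambda spec: alpha_accuracy(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "model_comparison": lambda spec: pd.concat(
        model_comparison(replicates=spec.replicates, scale=spec.scale,
                         seed=spec.seed, **spec.params),
        names=["protocol"],
    ).reset_index(level=0),
    "allsnps": lambda spec: allsnps_comparison(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "combined_degradation": lambda spec: combined_degradation(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "reference_geneflow": lambda spec: reference_geneflow(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "many_refs": lambda spec: many_refs(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "continuous_after_pulse": lambda spec: continuous_after_pulse(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    ),
    "stepping_stone": lambda spec: stepping_stone(
        replicates=spec.replicates, scale=spec.scale, seed=spec.seed, **spec.params
    )["fits"],
}


@dataclass
class ExperimentSpec:
    """A named experiment with its replicate count, genome scale and seed."""

    name: str
    replicates: int = 20
    scale: float = 1 / 400
    seed: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {sorted(EXPERIMENTS)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")


def run_experiment(spec: ExperimentSpec, out_dir: str | os.PathLike | None = None) -> pd.DataFrame:
    """Run one experiment; optionally write its table and a summary JSON."""
    table = EXPERIMENTS[spec.name](spec)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, f"{spec.name}.tsv"), sep="\t", index=False)
        summary = {
            "spec": dataclasses.asdict(spec),
            "n_rows": int(len(table)),
            "columns": list(table.columns),
        }
        with open(os.path.join(out_dir, f"{spec.name}.summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
    return table
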