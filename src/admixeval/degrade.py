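"""Data-quality corruption operators for genotype matrices.

Each operator models one artifact of real (especially ancient) DNA data:
random site down-sampling, per-individual missingness, pseudohaploid calling,
post-mortem deamination damage at transition sites, heterozygote-based
ascertainment, and reduced sample sizes.  All operators are pure (they
return a new matrix), independently seedable, preserve site order, and log
themselves into the matrix's provenance list.

Damage is applied per allele copy: at a flagged transition site, each
*reference* allele copy of an affected individual flips to the alternative
allele independently with probability ``d`` (genotype ``g`` becomes
``g + Binomial(2 - g, d)``), which is the unidirectional reference-to-
alternative shift that deamination induces on C/T and G/A sites.  Damage
never decreases a genotype value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from admixeval.genotype import MISSING, GenotypeMatrix

#: Fraction of sites behaving as transitions in typical capture panels.
DEFAULT_TRANSITION_FRACTION = 0.776
#: Default per-copy damage probability (an extreme, fully deaminated library).
DEFAULT_DAMAGE_RATE = 0.05


def _logged(G: GenotypeMatrix, entry: dict) -> GenotypeMatrix:
    G.provenance.append(entry)
    return G


def downsample_sites(G: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Uniform random subset of ``n`` sites without replacement, order kept."""
    if n > G.n_sites:
        raise ValueError(f"cannot downsample {G.n_sites} sites to {n}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(G.n_sites, size=n, replace=False))
    out = G.take_sites(keep)
    return _logged(out, {"op": "downsample_sites", "n": n, "seed": seed})


def apply_missingness(G: GenotypeMatrix, rate: float, seed: int,
                      exact: bool = False) -> GenotypeMatrix:
    """Set each (site, individual) call to MISSING independently with
    probability ``rate``.

    With ``exact=True`` every individual instead has exactly
    ``round(rate * n_sites)`` randomly chosen sites removed; the expected
    site-intersection arithmetic is the same either way.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    out = G.take_sites(np.arange(G.n_sites))
    if rate > 0.0 and G.n_sites:
        rng = np.random.default_rng(seed)
        if exact:
            k = int(round(rate * G.n_sites))
            for j in range(G.n_individuals):
                idx = rng.choice(G.n_sites, size=k, replace=False)
                out.calls[idx, j] = MISSING
        else:
            drop = rng.random(out.calls.shape) < rate
            out.calls[drop] = MISSING
    return _logged(out, {"op": "apply_missingness", "rate": rate, "seed": seed,
                         "exact": exact})


def pseudohaploidize(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace each diploid call by a randomly drawn single allele.

    Heterozygotes become 0 or 2 with probability 1/2 each; homozygotes and
    missing calls are unchanged, so the output contains no value 1."""
    rng = np.random.default_rng(seed)
    out = G.take_sites(np.arange(G.n_sites))
    het = out.calls == 1
    if het.any():
        out.calls[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    return _logged(out, {"op": "pseudohaploidize", "seed": seed})


def assign_transitions(G: GenotypeMatrix, fraction: float, seed: int) -> GenotypeMatrix:
    """Flag a uniform random ``fraction`` of sites as transitions."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("transition fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = G.take_sites(np.arange(G.n_sites))
    flags = rng.random(out.n_sites) < fraction
    out.snps = out.snps.assign(is_transition=flags)
    return _logged(out, {"op": "assign_transitions", "fraction": fraction, "seed": seed})


def apply_damage(G: GenotypeMatrix, d: float, populations: list[str],
                 seed: int) -> GenotypeMatrix:
    """Deamination-style damage in the given populations.

    At each flagged transition site, every reference allele copy of each
    affected individual flips to the alternative allele independently with
    probability ``d``; missing calls are untouched.  Requires
    :func:`assign_transitions` to have run first.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError("damage rate must be in [0, 1)")
    if "is_transition" not in G.snps.columns:
        raise ValueError("no transition flags assigned; run assign_transitions first")
    rng = np.random.default_rng(seed)
    out = G.take_sites(np.arange(G.n_sites))
    if d > 0.0 and populations:
        cols = np.concatenate([out.population_columns(p) for p in populations])
        tr = out.snps["is_transition"].to_numpy()
        sub = out.calls[np.ix_(tr, cols)]
        valid = sub != MISSING
        ref_copies = np.where(valid, 2 - sub, 0)
        flips = rng.binomial(ref_copies, d).astype(np.int8)
        out.calls[np.ix_(tr, cols)] = np.where(valid, sub + flips, sub)
    return _logged(out, {"op": "apply_damage", "d": d, "populations": list(populations),
                         "seed": seed})


def ascertain_het(G: GenotypeMatrix, panel_population: str, seed: int) -> GenotypeMatrix:
    """Restrict to sites heterozygous in one randomly chosen panel individual.

    The panel individual is drawn from ``panel_population`` and excluded from
    the returned matrix (it defined the site set and must not be analyzed).
    """
    rng = np.random.default_rng(seed)
    cols = G.population_columns(panel_population)
    panel = int(rng.choice(cols))
    het_sites = np.flatnonzero(G.calls[:, panel] == 1)
    if het_sites.size == 0:
        raise ValueError(
            f"panel individual {G.individuals['sample_id'].iloc[panel]!r} has no "
            "heterozygous site"
        )
    keep_inds = np.setdiff1d(np.arange(G.n_individuals), [panel])
    out = G.take_sites(het_sites).take_individuals(keep_inds)
    return _logged(out, {
        "op": "ascertain_het", "panel_population": panel_population,
        "panel_individual": str(G.individuals["sample_id"].iloc[panel]), "seed": seed,
    })


def reduce_sample_size(G: GenotypeMatrix, population: str, n: int, seed: int) -> GenotypeMatrix:
    """Keep a uniform random subset of ``n`` individuals of one population."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    cols = G.population_columns(population)
    if n > cols.size:
        raise ValueError(f"population {population!r} has only {cols.size} individuals")
    rng = np.random.default_rng(seed)
    drop = rng.choice(cols, size=cols.size - n, replace=False)
    keep = np.setdiff1d(np.arange(G.n_individuals), drop)
    out = G.take_individuals(keep)
    return _logged(out, {"op": "reduce_sample_size", "population": population,
                         "n": n, "seed": seed})


@dataclass
class DegradeConfig:
    """A stack of corruption operators applied in ancient-DNA processing
    order: down-sample -> ascertain -> transitions -> damage ->
    pseudohaploid -> missingness -> sample sizes."""

    downsample_sites: int | None = None
    ascertainment: str | None = None  # panel population label
    transition_fraction: float = DEFAULT_TRANSITION_FRACTION
    damage_rate: float = 0.0
    damage_populations: list[str] = field(default_factory=list)
    pseudohaploid: bool = False
    missing_rate: float = 0.0
    sample_sizes: dict[str, int] = field(default_factory=dict)


def apply_degradation(G: GenotypeMatrix, config: DegradeConfig, seed: int) -> GenotypeMatrix:
    """Apply a full degradation stack; each step gets its own derived seed."""
    ss = np.random.SeedSequence(seed).generate_state(8) % (2**31 - 1)
    out = G
    if config.downsample_sites is not None:
        out = downsample_sites(out, config.downsample_sites, int(ss[0]))
    if config.ascertainment is not None:
        out = ascertain_het(out, config.ascertainment, int(ss[1]))
    if config.damage_rate > 0.0 and config.damage_populations:
        out = assign_transitions(out, config.transition_fraction, int(ss[2]))
        out = apply_damage(out, config.damage_rate, config.damage_populations, int(ss[3]))
    if config.pseudohaploid:
        out = pseudohaploidize(out, int(ss[4]))
    if config.missing_rate > 0.0:
        out = apply_missingness(out, config.missing_rate, int(ss[5]))
    for pop, n in config.sample_sizes.items():
        out = reduce_sample_size(out, pop, n, int(ss[6]))
    return out
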