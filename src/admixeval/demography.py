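"""Demographic scenarios and coalescent simulation of genotype matrices.

A :class:`DemographyScenario` is a rooted population tree (splits) decorated
with admixture pulses and continuous migration, in forward-time semantics.
:func:`simulate_genotypes` turns a scenario into a diploid
:class:`~admixeval.genotype.GenotypeMatrix` via msprime, one coalescent
simulation per chromosome.

The standard 16-population scenario has two admixture pulses: a recent
two-way pulse forming population 14 (proportion ``alpha`` from a lineage
related to populations 5/6, ``1 - alpha`` from the lineage population 9
splits from at generation 280) and an older pulse forming population 15
(``beta = 0.55``).  Split times and effective sizes were chosen so that the
in-group populations 0-6 are closely related (average pairwise FST among
populations 1-5 in the low 1e-3 range) while deeper branches provide
differentially related reference populations.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from admixeval.genotype import MISSING, GenotypeMatrix

# Human autosome lengths (GRCh38, bp); scaled by SimulationConfig.scale.
HUMAN_AUTOSOME_LENGTHS = [
    248956422, 242193529, 198295559, 190214555, 181538259, 170805979,
    159345973, 145138636, 138394717, 133797422, 135086622, 133275309,
    114364328, 107043718, 101991189, 90338345, 83257441, 80373285,
    58617616, 64444167, 46709983, 50818468,
]

#: Fixed proportion of the older admixture pulse forming population 15.
BETA = 0.55

# Effective sizes (diploid).  The in-group uses a smaller size so that the
# pairwise FST among populations 1-5 lands in the observed low-1e-3 window.
NE_INGROUP = 35_000.0
NE_DEEP = 40_000.0
NE_STEPPING = 5_000.0

# Standard-model roles used throughout the experiments.
STANDARD_TARGET = "14"
STANDARD_SOURCES = ("5", "9")
STANDARD_REFERENCES = ("0", "7", "10", "12", "13")


@dataclass
class AdmixturePulse:
    """Instantaneous two-way admixture: at ``time`` generations ago the
    ``recipient`` population is formed from ``donors`` with the given
    donor-1 ``proportion`` (donor 2 contributes the complement)."""

    time: float
    recipient: str
    donors: tuple[str, str]
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"admixture proportion {self.proportion} outside [0, 1]")


@dataclass
class MigrationEdge:
    """Gene flow from ``source`` into ``dest`` (forward in time).

    ``rate`` is a per-generation migration fraction if ``pulse_time`` is
    None, otherwise a one-off pulse proportion at ``pulse_time``.
    Continuous migration runs from ``start_time`` (recent) back to
    ``end_time`` generations ago.
    """

    source: str
    dest: str
    rate: float
    pulse_time: float | None = None
    start_time: float = 0.0
    end_time: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"migration rate {self.rate} outside [0, 1]")


@dataclass
class Split:
    """At ``time`` generations ago the ``derived`` populations merge into
    ``ancestral`` (a forward-time branching event)."""

    time: float
    derived: list[str]
    ancestral: str


@dataclass
class DemographyScenario:
    """Population tree plus pulses and migrations, consumable by msprime.

    ``populations`` maps internal msprime-safe names to diploid effective
    sizes; ``labels`` maps those names to the external population labels used
    in genotype metadata (leaves only).
    """

    name: str
    populations: dict[str, float]
    splits: list[Split]
    pulses: list[AdmixturePulse] = field(default_factory=list)
    migrations: list[MigrationEdge] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)

    # -- structure ----------------------------------------------------------
    def leaf_names(self) -> list[str]:
        """Sampled (labelled) populations, in label order."""
        return list(self.labels)

    def label_of(self, name: str) -> str:
        return self.labels.get(name, name)

    def name_of(self, label: str) -> str:
        for name, lab in self.labels.items():
            if lab == label:
                return name
        raise KeyError(f"no population with label {label!r}")

    def lineage_at(self, name: str, time: float) -> str:
        """Population carrying ``name``'s ancestry at ``time`` generations ago
        (follows splits; admixture pulses are not traversed)."""
        current = name
        while True:
            nxt = None
            for s in sorted(self.splits, key=lambda s: s.time):
                if current in s.derived and s.time <= time:
                    nxt = s.ancestral
                    break
            if nxt is None:
                return current
            current = nxt

    # -- msprime ------------------------------------------------------------
    def to_msprime(self) -> msprime.Demography:
        d = msprime.Demography()
        for name, size in self.populations.items():
            d.add_population(name=name, initial_size=size)
        for p in self.pulses:
            d.add_admixture(
                time=p.time, derived=p.recipient, ancestral=list(p.donors),
                proportions=[p.proportion, 1.0 - p.proportion],
            )
        for s in self.splits:
            d.add_population_split(time=s.time, derived=list(s.derived), ancestral=s.ancestral)
        for m in self.migrations:
            if m.pulse_time is not None:
                # Forward: at pulse_time, `dest` receives fraction `rate` of its
                # ancestry from `source`.  Backwards (msprime mass migration):
                # lineages in `dest` move to `source` with probability `rate`.
                d.add_mass_migration(
                    time=m.pulse_time, source=m.dest, dest=m.source, proportion=m.rate
                )
            else:
                # Forward migration source -> dest corresponds to backwards
                # lineage movement dest -> source.
                if m.start_time == 0.0:
                    d.set_migration_rate(source=m.dest, dest=m.source, rate=m.rate)
                else:
                    d.add_migration_rate_change(
                        time=m.start_time, source=m.dest, dest=m.source, rate=m.rate
                    )
                if m.end_time is not None:
                    d.add_migration_rate_change(
                        time=m.end_time, source=m.dest, dest=m.source, rate=0.0
                    )
        d.sort_events()
        return d

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "populations": self.populations,
            "splits": [dataclasses.asdict(s) for s in self.splits],
            "pulses": [dataclasses.asdict(p) for p in self.pulses],
            "migrations": [dataclasses.asdict(m) for m in self.migrations],
            "labels": self.labels,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DemographyScenario":
        payload = json.loads(text)
        return cls(
            name=payload["name"],
            populations=payload["populations"],
            splits=[Split(**s) for s in payload["splits"]],
            pulses=[
                AdmixturePulse(
                    time=p["time"], recipient=p["recipient"],
                    donors=tuple(p["donors"]), proportion=p["proportion"],
                )
                for p in payload["pulses"]
            ],
            migrations=[MigrationEdge(**m) for m in payload["migrations"]],
            labels=payload["labels"],
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DemographyScenario":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

# Branch extents of the standard tree (name -> (start, end) generations ago),
# derived from the split times below; used for star placement in the
# many-populations scenario.
_STANDARD_SPLITS = [
    Split(50, ["p5", "p6"], "anc56"),
    Split(80, ["p0", "p1"], "anc01"),
    Split(110, ["anc01", "p2"], "anc012"),
    Split(140, ["anc012", "p3"], "anc0123"),
    Split(170, ["anc0123", "p4"], "anc04"),
    Split(235, ["p8", "p9"], "anc89"),
    Split(245, ["anc56", "a14"], "anc5a"),
    Split(280, ["anc89", "b14"], "ancB"),
    Split(310, ["anc04", "anc5a"], "ancA"),
    Split(400, ["p11", "a15"], "anc11"),
    Split(500, ["ancB", "b15"], "ancB2"),
    Split(1500, ["ancA", "ancB2"], "ancAB"),
    Split(1800, ["ancAB", "p7"], "anc7"),
    Split(2200, ["anc7", "p10"], "anc10"),
    Split(3600, ["anc10", "anc11"], "anc11x"),
    Split(4200, ["anc11x", "p12"], "anc12"),
    Split(5000, ["anc12", "p13"], "root"),
]

_INGROUP = {"p0", "p1", "p2", "p3", "p4", "p5", "p6", "p14", "a14",
            "anc56", "anc01", "anc012", "anc0123", "anc04", "anc5a", "ancA"}

ALPHA_PULSE_TIME = 100.0
BETA_PULSE_TIME = 350.0
#: Generation at which population 9 splits from the 14b donor lineage.
SOURCE9_SPLIT_TIME = 280.0


def _standard_populations() -> dict[str, float]:
    pops = {}
    names = [f"p{i}" for i in range(16)] + ["a14", "b14", "a15", "b15"] + [
        s.ancestral for s in _STANDARD_SPLITS
    ]
    for name in names:
        pops[name] = NE_INGROUP if name in _INGROUP or name in (
            "p8", "p9", "b14", "anc89", "ancB", "p15", "a15", "b15"
        ) else NE_DEEP
    return pops


def build_standard_tree(alpha: float = 0.5) -> DemographyScenario:
    """The 16-population base scenario with its two admixture pulses.

    ``alpha`` is the proportion of population 14's ancestry drawn from the
    lineage related to populations 5/6; the complement comes from the lineage
    that population 9 splits from at generation 280.  The older pulse forming
    population 15 is fixed at ``beta = 0.55`` regardless of ``alpha``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return DemographyScenario(
        name="standard",
        populations=_standard_populations(),
        splits=list(_STANDARD_SPLITS),
        pulses=[
            AdmixturePulse(ALPHA_PULSE_TIME, "p14", ("a14", "b14"), alpha),
            AdmixturePulse(BETA_PULSE_TIME, "p15", ("a15", "b15"), BETA),
        ],
        labels={f"p{i}": str(i) for i in range(16)},
    )


def build_reference_geneflow_tree(
    alpha: float,
    gamma: float,
    pulse_generation: float,
    donor: str = "10",
    recipient: str = "9",
) -> DemographyScenario:
    """Standard tree plus a single extra gene-flow pulse between a reference
    and a source lineage.

    ``gamma`` is the pulse proportion; ``pulse_generation`` of 200 (after the
    recipient's split from the 14b donor lineage at generation 280, i.e., a
    model violation) or 350 (before it, harmless) reproduce the two studied
    regimes.  ``donor``/``recipient`` are external labels; the pulse is
    directed into whichever internal lineage carries the recipient's ancestry
    at that generation.
    """
    scenario = build_standard_tree(alpha)
    scenario.name = "reference_geneflow"
    if gamma > 0.0:
        src = scenario.lineage_at(scenario.name_of(donor), pulse_generation)
        dst = scenario.lineage_at(scenario.name_of(recipient), pulse_generation)
        if src == dst:
            raise ValueError("donor and recipient coincide at the pulse time")
        scenario.migrations.append(
            MigrationEdge(source=src, dest=dst, rate=gamma, pulse_time=pulse_generation)
        )
    return scenario


def _standard_branches() -> list[tuple[str, float, float]]:
    """(name, start, end) extents of every finite branch of the standard tree."""
    start = {f"p{i}": 0.0 for i in range(16)}
    end: dict[str, float] = {}
    for s in _STANDARD_SPLITS:
        for dname in s.derived:
            end[dname] = s.time
        start[s.ancestral] = s.time
    end["p14"], end["p15"] = ALPHA_PULSE_TIME, BETA_PULSE_TIME
    start["a14"], end["a14"] = ALPHA_PULSE_TIME, 245.0
    start["b14"], end["b14"] = ALPHA_PULSE_TIME, SOURCE9_SPLIT_TIME
    start["a15"], end["a15"] = BETA_PULSE_TIME, 400.0
    start["b15"], end["b15"] = BETA_PULSE_TIME, 500.0
    return [(n, start[n], end[n]) for n in sorted(start) if n in end]


def build_many_pops_tree(n_pairs: int = 51) -> DemographyScenario:
    """Standard tree densified with nested population pairs.

    ``n_pairs`` extra lineages branch off existing branches; each new lineage
    itself branches 50 generations after its attachment, adding two sampled
    populations per attachment point (default 51 pairs -> 118 populations).
    Attachment points are spread deterministically across all branches.
    """
    scenario = build_standard_tree(0.5)
    scenario.name = "many_pops"

    branches = _standard_branches()
    slots: list[list[tuple[str, float]]] = []
    for name, lo, hi in branches:
        times = np.arange(max(lo, 0.0) + 60.0, hi - 4.0, 100.0)
        slots.append([(name, float(t)) for t in times if t - 50.0 > 1.0])
    chosen: list[tuple[str, float]] = []
    level = 0
    while len(chosen) < n_pairs:
        progressed = False
        for s in slots:
            if level < len(s):
                chosen.append(s[level])
                progressed = True
                if len(chosen) == n_pairs:
                    break
        if not progressed:
            raise ValueError(f"cannot place {n_pairs} branch pairs on the tree")
        level += 1

    next_label = 16
    for k, (branch, t) in enumerate(chosen):
        ne = scenario.populations[branch]
        a, b, anc = f"s{k}_a", f"s{k}_b", f"s{k}_anc"
        for nm in (a, b, anc):
            scenario.populations[nm] = ne
        scenario.splits.append(Split(t - 50.0, [a, b], anc))
        # Full merge of the pair's stem back into the host branch at time t.
        scenario.migrations.append(
            MigrationEdge(source=branch, dest=anc, rate=1.0, pulse_time=t)
        )
        scenario.labels[a] = str(next_label)
        scenario.labels[b] = str(next_label + 1)
        next_label += 2
    return scenario


#: Generation of the initial pulse in the continuous-gene-flow scenario:
#: immediately after the 14a donor lineage splits from population 5's
#: lineage at generation 245.
CONTINUOUS_PULSE_TIME = 240.0


def build_continuous_after_pulse(alpha: float, m: float) -> DemographyScenario:
    """Standard tree with the main pulse moved to generation 240 followed by
    continuous gene flow from populations 5 and 9 into 14 at rate ``m``
    per generation until the present."""
    scenario = build_standard_tree(alpha)
    scenario.name = "continuous_after_pulse"
    scenario.pulses[0] = AdmixturePulse(
        CONTINUOUS_PULSE_TIME, "p14", ("a14", "b14"), alpha
    )
    if m > 0.0:
        for donor in ("p5", "p9"):
            scenario.migrations.append(
                MigrationEdge(source=donor, dest="p14", rate=m, start_time=0.0)
            )
    return scenario


def build_stepping_stone(m: float) -> DemographyScenario:
    """Linear chain of six demes exchanging migrants, plus three outgroups.

    Demes 0-5 (Ne 5,000 each) split simultaneously from a common ancestor
    1000 generations ago and exchange migrants with chain neighbours at rate
    ``m`` per generation thereafter; the three outgroups 6-8 and the chain
    ancestor all split from the root 2000 generations ago.
    """
    if m < 0:
        raise ValueError("migration rate must be non-negative")
    pops = {f"d{i}": NE_STEPPING for i in range(6)}
    pops.update({f"o{i}": NE_STEPPING for i in (6, 7, 8)})
    pops.update({"anc_chain": NE_STEPPING, "root": NE_STEPPING})
    migrations = []
    if m > 0:
        for i in range(5):
            migrations.append(MigrationEdge(source=f"d{i}", dest=f"d{i+1}", rate=m))
            migrations.append(MigrationEdge(source=f"d{i+1}", dest=f"d{i}", rate=m))
    labels = {f"d{i}": str(i) for i in range(6)}
    labels.update({f"o{i}": str(i) for i in (6, 7, 8)})
    return DemographyScenario(
        name="stepping_stone",
        populations=pops,
        splits=[
            Split(1000, [f"d{i}" for i in range(6)], "anc_chain"),
            Split(2000, ["anc_chain", "o6", "o7", "o8"], "root"),
        ],
        migrations=migrations,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the coalescent simulation.

    ``scale`` multiplies the 22 human autosome lengths; mutation and
    recombination rates are the human-like defaults (1.5e-8 and 1.0e-8 per bp
    per generation).  ``samples_per_population`` is the number of diploid
    individuals sampled per population (an int, or a dict of external labels
    to override individual populations; a population absent from the dict
    falls back to the int default, and 0 skips it).
    """

    mutation_rate: float = 1.5e-8
    recombination_rate: float = 1.0e-8
    scale: float = 1.0
    chromosome_lengths: list[int] | None = None
    samples_per_population: int | dict[str, int] = 10
    seed: int = 1

    def lengths(self) -> list[int]:
        base = self.chromosome_lengths or HUMAN_AUTOSOME_LENGTHS
        return [max(int(L * self.scale), 1000) for L in base]

    def n_samples(self, label: str) -> int:
        if isinstance(self.samples_per_population, dict):
            return int(self.samples_per_population.get(label, 0))
        return int(self.samples_per_population)


def _site_alleles(ts) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and first-derived allele (single chars) per site, vectorized."""
    tables = ts.tables
    anc_off = tables.sites.ancestral_state_offset
    anc_chars = np.frombuffer(tables.sites.ancestral_state, dtype="S1")
    ref = anc_chars[anc_off[:-1]]
    der_off = tables.mutations.derived_state_offset
    der_chars = np.frombuffer(tables.mutations.derived_state, dtype="S1")
    mut_site = tables.mutations.site
    first_mut = np.full(ts.num_sites, -1, dtype=np.int64)
    # mutations are sorted by site; keep the first mutation of each site
    sites, first_idx = np.unique(mut_site, return_index=True)
    first_mut[sites] = first_idx
    alt = np.where(first_mut >= 0, der_chars[der_off[np.maximum(first_mut, 0)]], b"N")
    return ref.astype("U1"), alt.astype("U1")


def simulate_genotypes(
    scenario: DemographyScenario, config: SimulationConfig
) -> GenotypeMatrix:
    """Simulate a diploid genotype matrix under ``scenario``.

    Each chromosome is an independent coalescent-with-recombination
    simulation; mutations follow a nucleotide model and only strictly
    biallelic polymorphic sites are retained.  Diploid individuals are pairs
    of simulated haploid genomes from the same population.  Deterministic
    given ``config.seed``.
    """
    demog = scenario.to_msprime()
    sampled = [
        (name, scenario.label_of(name), config.n_samples(scenario.label_of(name)))
        for name in scenario.leaf_names()
    ]
    sampled = [(n, lab, k) for (n, lab, k) in sampled if k > 0]
    if not sampled:
        raise ValueError("no population has a positive sample size")
    samples = {name: k for name, _, k in sampled}

    lengths = config.lengths()
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(lengths))
    seeds = (seeds % (2**31 - 2)) + 1

    snp_frames = []
    call_chunks = []
    for ci, L in enumerate(lengths):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demog,
            ploidy=2,
            sequence_length=L,
            recombination_rate=config.recombination_rate,
            random_seed=int(seeds[2 * ci]),
            record_provenance=False,
        )
        ts = msprime.sim_mutations(ts, rate=config.mutation_rate,
                                   random_seed=int(seeds[2 * ci + 1]))
        if ts.num_sites == 0:
            continue
        H = ts.genotype_matrix().astype(np.int8, copy=False)
        # biallelic, polymorphic in the sample
        hi = H.max(axis=1)
        keep = (hi == 1) & (H.min(axis=1) == 0)
        H = H[keep]
        if H.shape[0] == 0:
            continue
        diploid = H[:, 0::2] + H[:, 1::2]
        positions = ts.tables.sites.position[keep].astype(np.int64) + 1
        ref, alt = _site_alleles(ts)
        ref, alt = ref[keep], alt[keep]
        # discrete-genome duplicates: keep the first site at each position
        uniq = np.concatenate([[True], np.diff(positions) > 0])
        diploid, positions, ref, alt = diploid[uniq], positions[uniq], ref[uniq], alt[uniq]
        ids = np.char.add(f"chr{ci + 1}_", positions.astype(str))
        snp_frames.append(pd.DataFrame({
            "snp_id": ids,
            "chromosome": ci + 1,
            "genetic_pos": positions * config.recombination_rate,
            "physical_pos": positions,
            "ref": ref,
            "alt": alt,
        }))
        call_chunks.append(diploid)

    if not snp_frames:
        import warnings

        warnings.warn("simulation produced no variant sites")
        snps = pd.DataFrame(columns=["snp_id", "chromosome", "genetic_pos",
                                     "physical_pos", "ref", "alt"])
        calls = np.empty((0, 2 * sum(samples.values()) // 2), dtype=np.int8)
    else:
        snps = pd.concat(snp_frames, ignore_index=True)
        calls = np.vstack(call_chunks)

    ind_rows = []
    for name, label, k in sampled:
        for j in range(k):
            ind_rows.append((f"{label}_{j}", "U", label))
    inds = pd.DataFrame(ind_rows, columns=["sample_id", "sex", "population"])
    G = GenotypeMatrix(snps=snps, individuals=inds, calls=calls)
    G.provenance.append({
        "op": "simulate", "scenario": scenario.name, "seed": config.seed,
        "scale": config.scale, "n_sites": G.n_sites,
    })
    return G
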