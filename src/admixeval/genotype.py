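"""Genotype data model, EIGENSTRAT I/O and population summaries.

Genotypes are stored internally as counts of the *alternative* (derived)
allele per diploid individual: 0, 1, 2, or :data:`MISSING`.  On disk the
EIGENSTRAT ``.geno`` convention (count of the reference allele, ``9`` for
missing) is used; the conversion happens at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Distinct from 0 everywhere.
MISSING: int = -1

SNP_COLUMNS = ["snp_id", "chromosome", "genetic_pos", "physical_pos", "ref", "alt"]
IND_COLUMNS = ["sample_id", "sex", "population"]


class EigenstratFormatError(ValueError):
    """Raised when an EIGENSTRAT file triplet is malformed."""


@dataclass
class GenotypeMatrix:
    """Sites x individuals table of alt-allele counts with SNP/sample metadata.

    Attributes
    ----------
    snps:
        DataFrame with columns ``snp_id, chromosome, genetic_pos (Morgans),
        physical_pos (bp, 1-based), ref, alt`` and optionally
        ``is_transition``.
    individuals:
        DataFrame with columns ``sample_id, sex, population``.
    calls:
        ``(n_sites, n_individuals)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    """

    snps: pd.DataFrame
    individuals: pd.DataFrame
    calls: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.snps), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.individuals)} individuals"
            )
        if len(self.individuals) and self.individuals["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in individuals")

    # -- basic introspection -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.individuals["population"]))

    def population_columns(self, population: str) -> np.ndarray:
        """Column indices of the individuals belonging to ``population``."""
        cols = np.flatnonzero((self.individuals["population"] == population).to_numpy())
        if cols.size == 0:
            raise KeyError(f"unknown population label {population!r}")
        return cols

    def is_pseudohaploid(self) -> bool:
        """True if no heterozygous call is present."""
        return not bool((self.calls == 1).any())

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        for chrom, sub in self.snps.groupby("chromosome", sort=False):
            pp = sub["physical_pos"].to_numpy()
            gp = sub["genetic_pos"].to_numpy()
            if np.any(np.diff(pp) <= 0):
                raise ValueError(f"physical positions not strictly increasing on chromosome {chrom}")
            if np.any(np.diff(gp) < 0):
                raise ValueError(f"genetic positions decreasing on chromosome {chrom}")
        if (self.snps["ref"] == self.snps["alt"]).any():
            raise ValueError("ref == alt at some site")

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to ``index`` (positions or boolean mask), order kept."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            snps=self.snps.iloc[index].reset_index(drop=True),
            individuals=self.individuals.copy(),
            calls=self.calls[index],
            provenance=list(self.provenance),
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given individual columns."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            snps=self.snps.copy(),
            individuals=self.individuals.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            provenance=list(self.provenance),
        )


# -- EIGENSTRAT I/O ---------------------------------------------------------

def read_eigenstrat(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read an EIGENSTRAT ``.geno``/``.snp``/``.ind`` triplet.

    The on-disk genotype character is the count of the *reference* allele
    (EIGENSTRAT semantics); it is converted to an alt-allele count in the
    returned matrix.  ``9`` maps to :data:`MISSING`.
    """
    prefix = os.fspath(prefix)
    snp_path, ind_path, geno_path = prefix + ".snp", prefix + ".ind", prefix + ".geno"
    for path in (snp_path, ind_path, geno_path):
        if not os.path.exists(path):
            raise FileNotFoundError(path)

    snps = pd.read_csv(
        snp_path, sep=r"\s+", header=None, names=SNP_COLUMNS,
        dtype={"snp_id": str, "chromosome": int, "genetic_pos": float,
               "physical_pos": int, "ref": str, "alt": str},
    ) if os.path.getsize(snp_path) else pd.DataFrame(columns=SNP_COLUMNS)
    inds = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=IND_COLUMNS, dtype=str,
    ) if os.path.getsize(ind_path) else pd.DataFrame(columns=IND_COLUMNS)

    n_ind = len(inds)
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if len(line) != n_ind:
                raise EigenstratFormatError(
                    f"{geno_path}:{lineno}: row has {len(line)} characters, "
                    f"expected {n_ind} (one per individual)"
                )
            rows.append(line)
    if len(rows) != len(snps):
        raise EigenstratFormatError(
            f"{geno_path}: {len(rows)} genotype rows but {len(snps)} SNPs in {snp_path}"
        )

    if rows:
        raw = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
        raw = raw.reshape(len(rows), n_ind)
        digits = raw - ord("0")
        ok = np.isin(digits, (0, 1, 2, 9))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise EigenstratFormatError(
                f"{geno_path}:{i + 1}: invalid genotype character {chr(raw[i, j])!r}"
            )
        calls = (2 - digits).astype(np.int8)  # ref count on disk -> alt count
        calls[digits == 9] = MISSING
    else:
        calls = np.empty((0, n_ind), dtype=np.int8)
    return GenotypeMatrix(snps=snps, individuals=inds, calls=calls)


def write_eigenstrat(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write ``G`` as an EIGENSTRAT triplet; lossless round trip with
    :func:`read_eigenstrat` (missing calls become ``9``)."""
    prefix = os.fspath(prefix)
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    with open(prefix + ".snp", "w") as fh:
        for rec in G.snps.itertuples(index=False):
            fh.write(
                f"{rec.snp_id}\t{rec.chromosome}\t{rec.genetic_pos:.8f}"
                f"\t{rec.physical_pos}\t{rec.ref}\t{rec.alt}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for rec in G.individuals.itertuples(index=False):
            fh.write(f"{rec.sample_id}\t{rec.sex}\t{rec.population}\n")
    disk = (2 - G.calls.astype(np.int16)).astype(np.uint8)
    disk[G.calls == MISSING] = 9
    chars = disk + ord("0")
    with open(prefix + ".geno", "wb") as fh:
        for row in chars:
            fh.write(row.tobytes() + b"\n")


# -- population summaries ---------------------------------------------------

def allele_counts(G: GenotypeMatrix, populations: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-population alt-allele sums and non-missing allele counts.

    Returns ``(alt_sum, n_alleles)``, both ``(n_pops, n_sites)`` float64.
    ``n_alleles`` is twice the number of non-missing diploid calls.
    """
    n_pops = len(populations)
    alt = np.empty((n_pops, G.n_sites))
    n = np.empty((n_pops, G.n_sites))
    for p, pop in enumerate(populations):
        cols = G.population_columns(pop)
        sub = G.calls[:, cols]
        miss = sub == MISSING
        alt[p] = np.where(miss, 0, sub).sum(axis=1)
        n[p] = 2.0 * (sub.shape[1] - miss.sum(axis=1))
    return alt, n


def allele_frequencies(G: GenotypeMatrix, populations: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-population per-site alt-allele frequencies.

    Returns ``(freq, n_alleles)`` with shape ``(n_pops, n_sites)``.  Sites
    where a population has no non-missing allele get ``freq = NaN``
    (undefined) and ``n_alleles = 0``.
    """
    alt, n = allele_counts(G, populations)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return freq, n


def shared_site_mask(G: GenotypeMatrix, populations: list[str]) -> np.ndarray:
    """Boolean mask of sites where every listed population has data.

    True iff each population has at least one non-missing allele at the site.
    Monotone: adding populations can only clear mask entries.
    """
    _, n = allele_counts(G, populations)
    return (n > 0).all(axis=0)


def pairwise_fst(G: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Hudson-type FST between two populations, as a ratio of averages.

    Per-site numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    denominator ``p1(1-p2) + p2(1-p1)`` are each summed over usable sites
    before the final division (Bhatia et al.'s recommended weighting).  Sites
    where either population has fewer than two observed alleles are skipped.
    """
    (f, n) = allele_frequencies(G, [pop_a, pop_b])
    usable = (n >= 2).all(axis=0)
    if not usable.any():
        raise ValueError("no site with >=2 alleles observed in both populations")
    p1, p2 = f[0, usable], f[1, usable]
    n1, n2 = n[0, usable], n[1, usable]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    den_sum = den.sum()
    if den_sum == 0:
        raise ValueError("no polymorphism between the two populations")
    return float(num.sum() / den_sum)


def pca_projection(G: GenotypeMatrix, populations: list[str] | None = None) -> pd.DataFrame:
    """Top-2 principal components of the normalized genotype matrix.

    Genotypes are mean-centered per site and scaled by ``sqrt(p(1-p))`` where
    ``p`` is the mean alt-allele frequency; monomorphic sites are dropped and
    missing calls imputed at the site mean.  Deterministic: each component's
    sign is fixed so that its largest-magnitude coordinate is positive.

    Returns a DataFrame with columns ``sample_id, population, PC1, PC2``.
    """
    if populations is None:
        populations = G.populations
    cols = np.concatenate([G.population_columns(p) for p in populations])
    sub = G.calls[:, cols].astype(float)
    sub[sub == MISSING] = np.nan
    if sub.shape[1] < 3:
        raise ValueError("PCA requires at least 3 individuals")
    mean = np.nanmean(sub, axis=1)
    p = mean / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if poly.sum() < 2:
        raise ValueError("PCA requires at least 2 polymorphic sites")
    sub = sub[poly]
    mean = mean[poly]
    p = p[poly]
    inds = np.where(np.isnan(sub))
    sub[inds] = mean[inds[0]]
    z = (sub - mean[:, None]) / np.sqrt(p * (1 - p))[:, None]
    # individuals x sites is small in the second dimension after the transpose
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    coords = u[:, :2] * s[:2]
    for k in range(2):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    meta = G.individuals.iloc[cols]
    return pd.DataFrame({
        "sample_id": meta["sample_id"].to_numpy(),
        "population": meta["population"].to_numpy(),
        "PC1": coords[:, 0],
        "PC2": coords[:, 1],
    })
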