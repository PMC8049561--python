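"""f4-statistics with weighted block-jackknife errors and covariances.

The f4-statistic for populations (A, B; C, D) is the average over usable
sites of ``(pA - pB) * (pC - pD)`` of sample allele frequencies.  Standard
errors and the covariance of a vector of f4-statistics are obtained by a
weighted delete-one-block jackknife over contiguous genomic blocks (default
0.05 Morgans), with block weights proportional to the number of sites each
block contributes.

Two site-handling policies are supported: under ``ALLSNPS_YES`` each
statistic uses the sites at which its own four populations all have data;
under ``ALLSNPS_NO`` every statistic is restricted to the sites shared by
*all* populations of the model.  The covariance is always estimated over one
common block partition; blocks that are empty for a component contribute
zero weight to that component.

Sample allele frequencies enter f4 without a small-sample correction: unlike
f2 and f3, f4 of four distinct population pairs is unbiased in the sample
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from admixeval.genotype import GenotypeMatrix, allele_counts

DEFAULT_BLOCK_SIZE = 0.05  # Morgans


class SitePolicy(str, Enum):
    ALLSNPS_YES = "yes"
    ALLSNPS_NO = "no"


@dataclass
class BlockPartition:
    """Non-overlapping site-index blocks, none spanning a chromosome."""

    block_size: float
    chromosomes: np.ndarray  # per block
    starts: np.ndarray  # site index of block start (inclusive)
    stops: np.ndarray  # site index of block end (exclusive)

    @property
    def n_blocks(self) -> int:
        return len(self.starts)

    @property
    def sizes(self) -> np.ndarray:
        return self.stops - self.starts


def make_blocks(snps: pd.DataFrame, block_size: float = DEFAULT_BLOCK_SIZE) -> BlockPartition:
    """Greedy partition of SNPs into jackknife blocks of ``block_size`` Morgans.

    Along each chromosome a new block starts as soon as the genetic distance
    from the current block's first SNP reaches ``block_size``; a SNP exactly
    at the boundary starts a new block.  Raises on non-monotone genetic
    positions.
    """
    if block_size <= 0:
        raise ValueError("block size must be positive")
    chroms, starts, stops = [], [], []
    gpos_all = snps["genetic_pos"].to_numpy()
    chrom_all = snps["chromosome"].to_numpy()
    offset = 0
    for chrom in pd.unique(chrom_all):
        idx = np.flatnonzero(chrom_all == chrom)
        gpos = gpos_all[idx]
        if np.any(np.diff(gpos) < 0):
            raise ValueError(f"genetic positions not non-decreasing on chromosome {chrom}")
        # block index of each SNP within this chromosome
        block_start_g = gpos[0]
        start = 0
        for i in range(1, len(gpos) + 1):
            if i == len(gpos) or gpos[i] - block_start_g >= block_size * (1 - 1e-9):
                chroms.append(chrom)
                starts.append(offset + start)
                stops.append(offset + i)
                if i < len(gpos):
                    start = i
                    block_start_g = gpos[i]
        offset += len(idx)
    return BlockPartition(
        block_size=block_size,
        chromosomes=np.asarray(chroms),
        starts=np.asarray(starts, dtype=np.int64),
        stops=np.asarray(stops, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Weighted block jackknife (Busing-style, block weights = site counts)
# ---------------------------------------------------------------------------

def _delete_one(total_sum, total_n, block_sums, block_ns):
    with np.errstate(invalid="ignore", divide="ignore"):
        return (total_sum - block_sums) / np.maximum(total_n - block_ns, 1e-300)


def jackknife_estimate(block_sums: np.ndarray, block_counts: np.ndarray) -> tuple[float, float]:
    """Weighted delete-one-block jackknife mean and standard error.

    ``block_sums[b]`` is the sum of per-site values in block ``b`` and
    ``block_counts[b]`` the number of contributing sites; the estimate is the
    ratio of totals and the SE follows the weighted jackknife variance
    formula (with equal-sized blocks this reduces to the classical
    delete-one jackknife).
    """
    block_sums = np.asarray(block_sums, dtype=float)
    block_counts = np.asarray(block_counts, dtype=float)
    nonempty = block_counts > 0
    if nonempty.sum() < 2:
        raise ValueError("jackknife requires at least 2 non-empty blocks")
    total_n = block_counts.sum()
    total_sum = block_sums.sum()
    theta = total_sum / total_n
    tau, _ = _pseudovalues(theta, total_sum, total_n, block_sums, block_counts)
    var = float((tau**2).sum() / nonempty.sum())
    return float(theta), float(np.sqrt(var))


def _pseudovalues(theta, total_sum, total_n, block_sums, block_ns):
    """Scaled jackknife residuals tau_b such that var = sum(tau^2) / B.

    Empty blocks get tau = 0 and do not contribute.
    """
    nonempty = block_ns > 0
    B = int(nonempty.sum())
    loo = _delete_one(total_sum, total_n, block_sums, block_ns)
    h = np.where(nonempty, total_n / np.maximum(block_ns, 1e-300), np.inf)
    with np.errstate(invalid="ignore"):
        theta_J = B * theta - ((1.0 - block_ns / total_n) * loo)[nonempty].sum()
        tau = np.where(
            nonempty,
            (h * theta - (h - 1.0) * loo - theta_J) / np.sqrt(np.maximum(h - 1.0, 1e-300)),
            0.0,
        )
    return tau, loo


# ---------------------------------------------------------------------------
# f4 machinery
# ---------------------------------------------------------------------------

class F4Workspace:
    """Precomputed per-population allele statistics for one genotype matrix.

    Holds alt-allele sums, allele counts and the block partition so that many
    f4-statistics (many candidate models) can be evaluated cheaply on the
    same data.
    """

    def __init__(self, G: GenotypeMatrix, populations: list[str] | None = None,
                 block_size: float = DEFAULT_BLOCK_SIZE):
        self.G = G
        self.populations = list(populations) if populations is not None else G.populations
        self.index = {p: i for i, p in enumerate(self.populations)}
        alt, n = allele_counts(G, self.populations)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        self.has_data = n > 0
        self.blocks = make_blocks(G.snps, block_size)

    def _pop(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise KeyError(f"population {label!r} not in workspace") from None

    def f4_block_sums(self, A: str, B: str, C: str, D: str,
                      mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-block sums of (pA-pB)(pC-pD) and usable-site counts.

        ``mask`` restricts the usable sites (e.g. a global shared-site mask);
        sites where any of the four populations lacks data are always
        excluded.
        """
        ia, ib, ic, id_ = (self._pop(x) for x in (A, B, C, D))
        usable = self.has_data[ia] & self.has_data[ib] & self.has_data[ic] & self.has_data[id_]
        if mask is not None:
            usable = usable & mask
        prod = (self.freq[ia] - self.freq[ib]) * (self.freq[ic] - self.freq[id_])
        prod = np.where(usable, prod, 0.0)
        sums = np.add.reduceat(prod, self.blocks.starts)
        counts = np.add.reduceat(usable.astype(np.float64), self.blocks.starts)
        # reduceat wraps for trailing empty slices only when starts==len; our
        # partition covers all sites so starts are always valid.
        return sums, counts

    def shared_mask(self, populations: list[str]) -> np.ndarray:
        rows = [self._pop(p) for p in populations]
        return self.has_data[rows].all(axis=0)


def f4(G: GenotypeMatrix, A: str, B: str, C: str, D: str,
       block_size: float = DEFAULT_BLOCK_SIZE,
       mask: np.ndarray | None = None) -> tuple[float, float]:
    """Point estimate and jackknife SE of f4(A, B; C, D).

    Average over usable sites of ``(pA - pB)(pC - pD)``; swapping A and B (or
    C and D) flips the sign, and ``A == B`` gives exactly 0.
    """
    ws = F4Workspace(G, populations=list(dict.fromkeys([A, B, C, D])), block_size=block_size)
    sums, counts = ws.f4_block_sums(A, B, C, D, mask=mask)
    if counts.sum() == 0:
        raise ValueError("no usable site for this f4-statistic")
    return jackknife_estimate(sums, counts)


@dataclass
class F4Vector:
    """A vector of f4-statistics with jackknife covariance.

    ``block_sums``/``block_counts`` have shape ``(n_stats, n_blocks)`` and
    allow cheap delete-one-block re-estimation.  The covariance is symmetric
    positive semi-definite (checked; symmetrized before the check).
    """

    quadruples: list[tuple[str, str, str, str]]
    estimates: np.ndarray
    covariance: np.ndarray
    block_sums: np.ndarray
    block_counts: np.ndarray
    policy: SitePolicy

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def to_frame(self) -> pd.DataFrame:
        """Tabular dump: one row per statistic with estimate, SE and Z."""
        se = self.standard_errors
        return pd.DataFrame({
            "A": [q[0] for q in self.quadruples],
            "B": [q[1] for q in self.quadruples],
            "C": [q[2] for q in self.quadruples],
            "D": [q[3] for q in self.quadruples],
            "f4": self.estimates,
            "se": se,
            "z": self.estimates / se,
            "n_sites": self.block_counts.sum(axis=1),
        })

    def delete_block(self, b: int) -> np.ndarray:
        """Vector of leave-block-``b``-out estimates."""
        tot_s = self.block_sums.sum(axis=1)
        tot_n = self.block_counts.sum(axis=1)
        return _delete_one(tot_s, tot_n, self.block_sums[:, b], self.block_counts[:, b])


def f4_vector_with_cov(
    G_or_ws: GenotypeMatrix | F4Workspace,
    quadruples: list[tuple[str, str, str, str]],
    policy: SitePolicy = SitePolicy.ALLSNPS_YES,
    block_size: float = DEFAULT_BLOCK_SIZE,
) -> F4Vector:
    """Estimates and jackknife covariance of a vector of f4-statistics.

    Under ``ALLSNPS_NO`` all statistics use the sites shared by every
    population appearing in ``quadruples``; under ``ALLSNPS_YES`` each uses
    its own four-population intersection.  The covariance is estimated by the
    weighted block jackknife over the common block partition.
    """
    if isinstance(G_or_ws, F4Workspace):
        ws = G_or_ws
    else:
        pops = list(dict.fromkeys([p for q in quadruples for p in q]))
        ws = F4Workspace(G_or_ws, populations=pops, block_size=block_size)

    policy = SitePolicy(policy)
    mask = None
    if policy is SitePolicy.ALLSNPS_NO:
        mask = ws.shared_mask(list(dict.fromkeys([p for q in quadruples for p in q])))

    d = len(quadruples)
    nb = ws.blocks.n_blocks
    sums = np.empty((d, nb))
    counts = np.empty((d, nb))
    for i, (a, b, c, dd) in enumerate(quadruples):
        sums[i], counts[i] = ws.f4_block_sums(a, b, c, dd, mask=mask)
        if counts[i].sum() == 0:
            raise ValueError(f"no usable site for f4{(a, b, c, dd)}")

    tot_s, tot_n = sums.sum(axis=1), counts.sum(axis=1)
    theta = tot_s / tot_n
    taus = np.empty((d, nb))
    for i in range(d):
        taus[i], _ = _pseudovalues(theta[i], tot_s[i], tot_n[i], sums[i], counts[i])
    n_nonempty = (counts > 0).sum(axis=1)
    # normalize per-component by its own non-empty block count
    scale = 1.0 / np.sqrt(n_nonempty.astype(float))
    C = (taus * scale[:, None]) @ (taus * scale[:, None]).T
    C = 0.5 * (C + C.T)
    eigmin = np.linalg.eigvalsh(C)[0]
    if eigmin < -1e-8 * max(np.trace(C), 1e-300):
        raise FloatingPointError("jackknife covariance is not positive semi-definite")
    return F4Vector(
        quadruples=list(quadruples), estimates=theta, covariance=C,
        block_sums=sums, block_counts=counts, policy=policy,
    )
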