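"""Base and rotating model-comparison protocols.

Given a target and a pool of candidate populations, the *base* protocol
evaluates every k-subset of candidates as sources against one fixed
reference set; the *rotating* protocol uses the same source subsets but
turns every non-source candidate into a reference, so that good alternative
sources always sit on the informative ("right") side of the models they are
not part of.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from admixeval.fstats import F4Workspace
from admixeval.genotype import GenotypeMatrix
from admixeval.qpadm import QpAdmFit, QpAdmModel, QpAdmOptions, qpadm


class ProtocolKind(str, Enum):
    BASE = "base"
    ROTATING = "rotating"


@dataclass
class SearchProtocol:
    """How candidate models for one target are generated."""

    kind: ProtocolKind
    candidates: list[str]
    k: int = 2
    base_references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kind = ProtocolKind(self.kind)
        if self.kind is ProtocolKind.BASE:
            if not self.base_references:
                raise ValueError("base protocol requires base_references")
            overlap = set(self.candidates) & set(self.base_references)
            if overlap:
                raise ValueError(f"candidates overlap base references: {sorted(overlap)}")


def enumerate_models(protocol: SearchProtocol, target: str) -> list[QpAdmModel]:
    """All candidate models for ``target`` under the protocol.

    BASE: every k-combination of candidates with the fixed reference set.
    ROTATING: the same combinations, with references = candidates minus the
    sources of each model.
    """
    cands = [c for c in protocol.candidates if c != target]
    models = []
    for sources in itertools.combinations(cands, protocol.k):
        if protocol.kind is ProtocolKind.BASE:
            refs = list(protocol.base_references)
        else:
            refs = [c for c in cands if c not in sources]
        models.append(QpAdmModel(target=target, sources=list(sources), references=refs))
    if not models:
        raise ValueError("no model can be formed from the candidate set")
    return models


def evaluate_models(
    replicates: list[GenotypeMatrix | F4Workspace],
    models: list[QpAdmModel],
    options: QpAdmOptions | None = None,
) -> pd.DataFrame:
    """Run every model on every replicate; aggregate plausibility.

    Returns one row per model with columns ``sources, n_replicates,
    n_plausible, plausible_fraction, mean_p, mean_weights``.
    """
    options = options or QpAdmOptions()
    if not replicates:
        raise ValueError("need at least one replicate")
    fits = fit_models_per_replicate(replicates, models, options)
    rows = []
    for j, model in enumerate(models):
        col = [fits[i][j] for i in range(len(replicates))]
        rows.append({
            "target": model.target,
            "sources": "+".join(model.sources),
            "n_replicates": len(col),
            "n_plausible": sum(f.plausible for f in col),
            "plausible_fraction": np.mean([f.plausible for f in col]),
            "mean_p": np.mean([f.p_value for f in col]),
            "mean_weights": np.mean([f.weights for f in col], axis=0).tolist(),
        })
    return pd.DataFrame(rows)


def fit_models_per_replicate(
    replicates: list[GenotypeMatrix | F4Workspace],
    models: list[QpAdmModel],
    options: QpAdmOptions | None = None,
) -> list[list[QpAdmFit]]:
    """Fits indexed ``[replicate][model]``, reusing per-replicate allele
    statistics across models."""
    options = options or QpAdmOptions()
    pops = sorted({p for m in models for p in m.all_populations})
    out = []
    for rep in replicates:
        if isinstance(rep, F4Workspace):
            ws = rep
        else:
            ws = F4Workspace(rep, populations=pops, block_size=options.block_size)
        out.append([qpadm(ws, m, options) for m in models])
    return out


def pvalue_uniformity(p_values: list[float] | np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of the P-values against U(0, 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 20:
        raise ValueError("need at least 20 P-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values outside [0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def pvalue_ranking_frequency(
    fits_per_replicate: list[list[QpAdmFit]], reference_index: int
) -> float:
    """Fraction of replicates in which the reference model attains the
    highest P-value among the competing models."""
    n_models = {len(fits) for fits in fits_per_replicate}
    if len(n_models) != 1:
        raise ValueError("replicates were not evaluated on the same model set")
    wins = 0
    for fits in fits_per_replicate:
        ps = [f.p_value for f in fits]
        if np.argmax(ps) == reference_index:
            wins += 1
    return wins / len(fits_per_replicate)
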