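"""Over-representation scoring with control-gene-set calibration.

Instead of a fixed p-value threshold, a query gene list's enrichment
p-values are compared against the minimum p-value achieved by k
equally sized control gene lists sampled at random from a pool of
similarly expressed genes: a pathway is called significant only when
its p-value is strictly below the best p any control set reached.
This calibrates the threshold to whatever multiplicity and background
structure the scorer and collection induce.

The scorer is the upper-tail hypergeometric test (pluggable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, tab-separated
    name / description / members."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{line_no}: GMT line needs name, description and "
                    f">=1 member"
                )
            name, members = parts[0], {g for g in parts[2:] if g}
            if name in sets:
                raise ValidationError(f"{path}:{line_no}: duplicate set {name!r}")
            if not members:
                raise ValidationError(f"{path}:{line_no}: empty set {name!r}")
            sets[name] = members
    return sets


def hypergeometric_ora(query, gene_set, universe):
    """Upper-tail hypergeometric over-representation p-value.

    p = P(overlap >= observed) drawing |query| genes from a universe of
    size N containing |set ∩ universe| marked genes. Returns
    ``(overlap, p)``. Query genes outside the universe raise.
    """
    query = set(query)
    universe = set(universe)
    outside = query - universe
    if outside:
        raise ValidationError(
            f"query gene(s) outside universe: {sorted(outside)[:5]}"
        )
    marked = set(gene_set) & universe
    overlap = len(query & marked)
    n_universe, n_marked, n_query = len(universe), len(marked), len(query)
    # P(X >= overlap), X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(overlap - 1, n_universe, n_marked, n_query))
    return overlap, min(p, 1.0)


@dataclass
class CalibratedEnrichmentResult:
    set_name: str
    overlap: int
    p: float
    threshold: float
    significant: bool  # p strictly below the calibration threshold


@dataclass
class CalibrationReport:
    threshold: float
    results: list[CalibratedEnrichmentResult]
    control_min_p: list[float] = field(default_factory=list)


def control_calibrated_enrichment(query, collections: dict[str, set[str]],
                                  similar_pool, universe, k_controls: int = 5,
                                  seed: int | None = None,
                                  scorer=hypergeometric_ora) -> CalibrationReport:
    """Score ``query`` against every set, calibrating significance on
    ``k_controls`` random control gene lists.

    Controls are sampled without replacement from ``similar_pool``
    (genes with near-equal expression in the two groups), each the
    same size as the query; every control is scored against every
    collection and the significance threshold is the global minimum p
    over all control scores. Query sets are flagged significant iff
    their p is strictly below that threshold.
    """
    query = sorted(set(query))
    pool = sorted(set(similar_pool))
    if len(pool) < len(query):
        raise ValidationError(
            f"similar pool ({len(pool)}) smaller than the query "
            f"({len(query)}); cannot draw size-matched controls"
        )
    if k_controls < 1:
        raise ValidationError("need at least one control set")
    rng = np.random.default_rng(seed)
    control_min_p = []
    threshold = np.inf
    for _ in range(k_controls):
        control = rng.choice(pool, size=len(query), replace=False)
        pmin = min(
            scorer(control, members, universe)[1]
            for members in collections.values()
        )
        control_min_p.append(float(pmin))
        threshold = min(threshold, pmin)
    results = []
    for name, members in collections.items():
        overlap, p = scorer(query, members, universe)
        results.append(
            CalibratedEnrichmentResult(
                set_name=name, overlap=overlap, p=p,
                threshold=float(threshold),
                significant=bool(p < threshold),
            )
        )
    return CalibrationReport(threshold=float(threshold), results=results,
                             control_min_p=control_min_p)
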