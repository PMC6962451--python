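"""Cross-effect set operations: Venn partitions, over-representation, concordance.

The Venn partition decomposes 2-4 named protein sets into exclusive regions
and reports each region's share of every contributing set's own total (the
"% of the respective protein sets" convention). Over-representation is a
neutral hypergeometric upper-tail test against caller-supplied annotation
sets (GMT format accepted); no pathway database is bundled. Direction
concordance compares the sign of log2 fold changes between two contrast
tables over a shared identifier space (e.g. protein vs transcript), the
identifier mapping being the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ValidationError

ENRICHMENT_COLUMNS = [
    "term", "overlap", "term_size", "query_size", "universe_size", "expected", "p", "q",
]


@dataclass(frozen=True)
class VennPartition:
    """Exclusive-region decomposition of named sets.

    ``regions`` maps a sorted tuple of set names (the region label) to the
    ids exclusive to exactly those sets; every non-empty subset of the input
    names is present, possibly with an empty id set.
    """

    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset[str]]
    per_effect_totals: dict[str, int]

    def region_size(self, *names: str) -> int:
        return len(self.regions[tuple(sorted(names, key=self.set_names.index))])

    def share_of(self, region: tuple[str, ...], name: str) -> float:
        """Size of a region as a fraction of one contributing set's total."""
        if name not in region:
            raise ValidationError(f"{name!r} does not contribute to region {region}")
        total = self.per_effect_totals[name]
        return len(self.regions[region]) / total if total else 0.0

    def to_json_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "per_effect_totals": dict(self.per_effect_totals),
            "regions": [
                {
                    "label": "&".join(region),
                    "size": len(ids),
                    "shares": {n: self.share_of(region, n) for n in region},
                    "ids": sorted(ids),
                }
                for region, ids in self.regions.items()
            ],
        }


def venn_partition(sets: Mapping[str, set]) -> VennPartition:
    """Partition 2-4 named id sets into exclusive Venn regions."""
    if not sets:
        raise ValidationError("venn_partition needs a non-empty mapping of sets")
    names = tuple(sets.keys())
    if not (2 <= len(names) <= 4):
        raise ValidationError(f"venn_partition takes 2-4 sets, got {len(names)}")
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = set()
    for element in set().union(*sets.values()):
        key = tuple(n for n in names if element in sets[n])
        regions[key].add(element)
    return VennPartition(
        set_names=names,
        regions={k: frozenset(v) for k, v in regions.items()},
        per_effect_totals={n: len(sets[n]) for n in names},
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read annotation sets in GMT format (term, description, member ids)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line needs term, description, >=1 member: {line!r}")
            out[parts[0]] = set(parts[2:])
    return out


def enrichment_test(
    query: set[str],
    universe: set[str],
    annotation_sets: Mapping[str, set[str]],
    fdr: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term within the query.

    Per term: p = P(X >= overlap) for X ~ Hypergeom(population |universe|,
    successes |term ∩ universe|, draws |query|). Annotation sets are
    intersected with the universe first; the query must be a subset of it.
    """
    stray = query - universe
    if stray:
        raise ConsistencyError(f"query ids outside universe: {sorted(stray)[:5]}")
    m = len(universe)
    n_query = len(query)
    rows = []
    for term, members in annotation_sets.items():
        in_universe = members & universe
        k = len(in_universe & query)
        term_size = len(in_universe)
        expected = term_size * n_query / m if m else 0.0
        p = float(stats.hypergeom.sf(k - 1, m, term_size, n_query)) if m else 1.0
        rows.append((term, k, term_size, n_query, m, expected, min(p, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size", "universe_size",
                       "expected", "p"],
    )
    if fdr and len(frame):
        from statsmodels.stats.multitest import multipletests

        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    else:
        frame["q"] = np.nan
    return frame


@dataclass(frozen=True)
class ConcordanceResult:
    """Sign agreement of fold changes between two contrast collections."""

    n_shared: int
    n_concordant: int
    fraction: float  # NaN when n_shared == 0

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_concordant": self.n_concordant,
            "fraction": None if math.isnan(self.fraction) else self.fraction,
        }


def direction_concordance(
    contrast_a: pd.DataFrame,
    contrast_b: pd.DataFrame,
    min_abs_log2_fc: float = 0.0,
) -> ConcordanceResult:
    """Fraction of shared ids whose log2 FC sign agrees in both contrasts.

    Only ids with |log2_fc| >= min_abs_log2_fc in *both* collections are
    compared; ties at log2_fc == 0 in either collection never count as
    concordant unless both are zero.
    """
    a = contrast_a.set_index("protein_id")["log2_fc"]
    b = contrast_b.set_index("protein_id")["log2_fc"]
    shared = a.index.intersection(b.index)
    a = a.loc[shared].to_numpy(dtype=float)
    b = b.loc[shared].to_numpy(dtype=float)
    keep = (
        ~np.isnan(a) & ~np.isnan(b)
        & (np.abs(a) >= min_abs_log2_fc) & (np.abs(b) >= min_abs_log2_fc)
    )
    a, b = a[keep], b[keep]
    n_shared = int(keep.sum())
    n_concordant = int(np.sum(np.sign(a) == np.sign(b)))
    fraction = n_concordant / n_shared if n_shared else float("nan")
    return ConcordanceResult(n_shared, n_concordant, fraction)
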