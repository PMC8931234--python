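"""Phenotype probabilities by uniform genotype sampling, and the
probability-complexity upper bound.

Uniform sampling of genotypes estimates the probability P(p) that the GP map
develops phenotype p; UND outcomes are tallied but excluded from the
normalization.  The central prediction tested with these tables is the
algorithmic-probability bound

    P(p) <= 2 ** (-a * K~(p) - b)

with map-dependent constants a >= 0 and b.  :func:`fit_bound` pins the
package's envelope-fitting convention: a least-squares line through the
per-integer-complexity-bin maxima of log2 P, with b then shifted minimally
so that no record violates the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import key_to_cells
from .polyomino import PolyominoGPMap, genotype_seed

#: reserved key for the UND tally in serialized tables
UND_KEY = "UND"


@dataclass
class FrequencyTable:
    """Phenotype counts and probabilities from one sampling experiment.

    Probabilities are normalized over non-UND outcomes only:
    P = count / (n_samples - n_und).
    """

    counts: dict
    n_samples: int
    n_und: int
    seed: int | None = None
    examples: dict = field(default_factory=dict, repr=False)

    @property
    def n_effective(self) -> int:
        return self.n_samples - self.n_und

    def probability(self, key) -> float:
        return self.counts.get(key, 0) / self.n_effective

    @property
    def probabilities(self) -> dict:
        ne = self.n_effective
        return {k: c / ne for k, c in self.counts.items()}

    def __len__(self):
        return len(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        ne = self.n_effective
        rows = [{"phenotype": serialize_key(k), "count": c,
                 "probability": c / ne, "size": phenotype_size(k)}
                for k, c in sorted(self.counts.items(),
                                   key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows,
                            columns=["phenotype", "count", "probability",
                                     "size"])


def serialize_key(key) -> str:
    """Human-readable serialization of a phenotype key."""
    if isinstance(key, bytes):
        if key and len(key) % 8 == 0:
            return ";".join(f"{x},{y}" for x, y in key_to_cells(key))
        return key.hex()
    return str(key)


def phenotype_size(key) -> int | None:
    return len(key) // 8 if isinstance(key, bytes) else None


def estimate_phenotype_frequencies(n_tiles: int = 16, bits_per_color: int = 6,
                                   num_samples: int = 10**6, seed: int = 0,
                                   cutoff: int = 16, repeats: int = 20,
                                   keep_examples: int = 0,
                                   chunk: int = 8192,
                                   gp_map: PolyominoGPMap | None = None
                                   ) -> FrequencyTable:
    """Estimate P(p) for an S(n, 4n) map by uniform genotype sampling.

    Genomes are drawn uniformly over all 2**L bit strings (equivalently,
    every interface color independently uniform).  Each genotype's assembly
    RNG is seeded from a digest of the genotype itself combined with
    ``seed``, so the same seed reproduces the table exactly and a genotype's
    phenotype does not depend on when it is drawn.  ``keep_examples`` > 0
    retains up to that many generating genotypes per phenotype for
    downstream minimal-genome complexity estimation.
    """
    if num_samples < 1:
        raise ValueError("num_samples must be >= 1")
    if gp_map is None:
        gp_map = PolyominoGPMap(n_tiles, bits_per_color, cutoff, repeats,
                                master_seed=seed)
    rng = np.random.default_rng(seed)
    counts: dict = {}
    examples: dict = {}
    n_und = 0
    remaining = num_samples
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        colors = gp_map.random_genotypes(m, rng)
        seeds = np.array([genotype_seed(colors[i], seed) for i in range(m)],
                         dtype=np.int64)
        keys = gp_map.phenotype_keys_batch(colors, seeds)
        for i, key in enumerate(keys):
            if key is None:
                n_und += 1
                continue
            counts[key] = counts.get(key, 0) + 1
            if keep_examples:
                ex = examples.setdefault(key, [])
                if len(ex) < keep_examples:
                    ex.append(colors[i].copy())
    return FrequencyTable(counts, num_samples, n_und, seed, examples)


@dataclass(frozen=True)
class BoundParams:
    """Constants of the probability-complexity upper bound
    P <= 2**(-a*K - b)."""

    a: float
    b: float

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("slope a must be nonnegative")


def ait_bound(K: float, params: BoundParams) -> float:
    """The upper bound 2**(-a*K - b) at complexity K >= 0."""
    if K < 0:
        raise ValueError("complexity must be nonnegative")
    return float(2.0 ** (-params.a * K - params.b))


def fit_bound(records) -> BoundParams:
    """Fit envelope constants (a, b) to (complexity, probability) records.

    Records are binned by integer complexity; a least-squares line is fit
    through (bin, log2 max-probability) and b is then shifted minimally so
    every record satisfies P <= 2**(-a*K - b) (zero violations by
    construction).  The slope is clipped at zero if the envelope rises.
    """
    recs = [(float(k), float(p)) for k, p in records if p > 0]
    if not recs:
        raise ValueError("no records with positive probability")
    bins: dict = {}
    for k, p in recs:
        key = int(round(k))
        bins[key] = max(bins.get(key, 0.0), p)
    if len(bins) < 2:
        raise ValueError("need records in at least 2 distinct complexity "
                         "bins to fit a slope")
    ks = np.array(sorted(bins), dtype=float)
    logp = np.log2([bins[int(k)] for k in ks])
    slope, intercept = np.polyfit(ks, logp, 1)
    a = max(0.0, -float(slope))
    # minimal shift of b so that log2 p <= -a k - b for every record
    b = min(-np.log2(p) - a * k for k, p in recs)
    return BoundParams(a, float(b))


def bound_violations(records, params: BoundParams, rtol: float = 1e-9) -> int:
    """Number of records with P > 2**(-a*K - b) beyond rounding error."""
    return sum(1 for k, p in records
               if p > (1 + rtol) * ait_bound(float(k), params))


def frequency_complexity_records(table: FrequencyTable, gp_map,
                                 min_count: int = 10,
                                 budget: int = 5) -> pd.DataFrame:
    """Attach minimal-genome interface complexities to a frequency table.

    Phenotypes observed at least ``min_count`` times (rarer ones suffer the
    low-frequency widening of finite sampling and would dominate runtime)
    are scored by :func:`simbias.complexity.minimal_interface_complexity`
    using up to ``budget`` of the generating genotypes retained by the
    sampler, which requires the table to have been built with
    ``keep_examples > 0``.  Returns a DataFrame with columns (phenotype,
    count, probability, size, complexity).
    """
    from .complexity import minimal_interface_complexity

    if not table.examples:
        raise ValueError("table has no stored example genotypes; sample "
                         "with keep_examples > 0")
    rows = []
    ne = table.n_effective
    for key, count in table.counts.items():
        if count < min_count:
            continue
        value = minimal_interface_complexity(key, table.examples[key],
                                             gp_map, budget=budget)
        rows.append({"phenotype": serialize_key(key), "count": count,
                     "probability": count / ne,
                     "size": phenotype_size(key),
                     "complexity": value.value})
    return pd.DataFrame(rows,
                        columns=["phenotype", "count", "probability",
                                 "size", "complexity"])


def compare_frequency_tables(table_a: FrequencyTable,
                             table_b: FrequencyTable):
    """Inner-join two frequency tables on phenotype key and correlate
    log-probabilities.

    Returns ``(dataframe, pearson_r, p_value)``; the dataframe has one row
    per shared phenotype with both probabilities.  Zero-count phenotypes
    never appear in a table, so the join excludes them naturally.
    """
    shared = sorted(set(table_a.counts) & set(table_b.counts))
    if len(shared) < 2:
        raise ValueError("tables share fewer than 2 phenotype keys")
    rows = [{"phenotype": serialize_key(k),
             "probability_a": table_a.probability(k),
             "probability_b": table_b.probability(k)} for k in shared]
    df = pd.DataFrame(rows)
    r, p = stats.pearsonr(np.log(df["probability_a"]),
                          np.log(df["probability_b"]))
    return df, float(r), float(p)
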