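"""Gene-set over-representation via the hypergeometric upper tail.

Given a query gene list (e.g. the mRNAs of a ceRNA subnetwork), a GMT
gene-set library, and a background universe (by default the mRNAs that
survived the expression filter), each set is scored with
P(X >= k) for X ~ Hypergeometric(N, K, n) — equivalently one-tailed
Fisher's exact — followed by Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .de import adjust_bh

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {set_name: (description, members)}.

    Duplicate member symbols within a set are collapsed with a warning;
    duplicate set names and lines with fewer than three fields are errors.
    """
    library: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, description, *members = fields
            if name in library:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                warnings.warn(f"set {name!r}: duplicate members collapsed")
            library[name] = (description, unique)
    if not library:
        raise ValueError(f"{path}: no gene sets")
    return library


def write_gmt(library: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (description, members) in library.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail p-value P(X >= k), X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k} K={K} n={n} N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    library: dict[str, tuple[str, list[str]]],
    universe,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every library set against ``universe``.

    Query members outside the universe are dropped (count logged); library
    sets are intersected with the universe. Rows are sorted by p ascending,
    ties lexicographic by set name; ``passed`` means q < fdr_threshold.
    """
    universe = set(universe)
    query_in = sorted(set(query) & universe)
    n_dropped = len(set(query)) - len(query_in)
    if n_dropped:
        logger.info("enrich: dropped %d query genes outside the universe", n_dropped)
    if not query_in:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(universe), len(query_in)
    qset = set(query_in)
    rows = []
    for name in sorted(library):
        _, members = library[name]
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & qset)
        p = hypergeometric_test(k, K, n, N) if K else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = adjust_bh(df["p"].to_numpy())
    df["neg_log10_p"] = -np.log10(df["p"])
    df["passed"] = df["q"] < fdr_threshold
    df = df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    return df


def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact enumeration of the upper tail with binomial coefficients.

    Kept in the library for small-N verification work; tests also carry an
    independent copy.
    """
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total
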