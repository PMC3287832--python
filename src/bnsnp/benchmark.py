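"""Published GAW17 mini-exome benchmark counts.

These are the reported subset-selection counts from a published
application of hill-climbing Bayesian-network structure learning
(log-likelihood score, 1,000 random restarts, 2,400 directional
perturbations) to the 533 SNPs of the 36 causal genes in the GAW17
mini-exome data, pooled into Asian, European and African ancestry
samples.  The underlying genotypes are workshop-distributed and not
public, but the printed counts (N, m per population and k/n per
replicate set and subset method) suffice to regenerate every reported
enrichment probability exactly, which is how this package validates its
hypergeometric machinery against the published tables.

``POPULATION_COUNTS`` maps ancestry -> (N polymorphic SNPs, m causal).
``SUBSET_COUNTS`` rows are (ancestry, replicate set, method, k, n,
printed tail probability as text).  One published cell (European 1-20
CA, "0/1 0.711") prints the point mass P(X = 0) = 138/194 instead of
the k = 0 tail (identically 1); it is retained verbatim and flagged.
"""

from __future__ import annotations

POPULATION_COUNTS: dict[str, tuple[int, int]] = {
    "Asian": (280, 87),
    "European": (194, 56),
    "African": (260, 59),
}

#: (ancestry, replicate_set, method, k, n, printed_p)
SUBSET_COUNTS: list[tuple[str, str, str, int, int, str]] = [
    ("Asian", "1-10", "DA", 12, 25, "0.0485"),
    ("Asian", "1-10", "MBA", 11, 45, "0.891"),
    ("Asian", "1-10", "CA", 2, 3, "0.228"),
    ("Asian", "11-20", "DA", 2, 7, "0.695"),
    ("Asian", "11-20", "MBA", 9, 36, "0.850"),
    ("Asian", "11-20", "CA", 0, 2, "1"),
    ("Asian", "1-20", "DA", 69, 182, "0.000467"),
    ("Asian", "1-20", "MBA", 15, 55, "0.798"),
    ("Asian", "1-20", "CA", 2, 7, "0.695"),
    ("Asian", "21-40", "DA", 15, 69, "0.983"),
    ("Asian", "21-40", "MBA", 24, 63, "0.113"),
    ("Asian", "21-40", "CA", 2, 4, "0.367"),
    ("Asian", "1", "DA", 77, 237, "0.152"),
    ("Asian", "1", "MBA", 63, 221, "0.973"),
    ("Asian", "1", "CA", 16, 54, "0.658"),
    ("Asian", "2", "DA", 75, 235, "0.305"),
    ("Asian", "2", "MBA", 55, 221, "0.999"),
    ("Asian", "2", "CA", 17, 64, "0.851"),
    ("Asian", "3", "DA", 74, 217, "0.0278"),
    ("Asian", "3", "MBA", 66, 190, "0.0355"),
    ("Asian", "3", "CA", 22, 43, "0.00227"),
    ("Asian", "4", "DA", 76, 227, "0.0479"),
    ("Asian", "4", "MBA", 55, 190, "0.894"),
    ("Asian", "4", "CA", 11, 42, "0.821"),
    ("Asian", "5", "DA", 76, 240, "0.371"),
    ("Asian", "5", "MBA", 66, 218, "0.758"),
    ("Asian", "5", "CA", 25, 68, "0.155"),
    ("Asian", "6", "DA", 74, 224, "0.102"),
    ("Asian", "6", "MBA", 55, 191, "0.909"),
    ("Asian", "6", "CA", 13, 45, "0.694"),
    ("Asian", "7", "DA", 67, 203, "0.160"),
    ("Asian", "7", "MBA", 60, 202, "0.826"),
    ("Asian", "7", "CA", 16, 55, "0.693"),
    ("Asian", "8", "DA", 65, 212, "0.663"),
    ("Asian", "8", "MBA", 66, 226, "0.937"),
    ("Asian", "8", "CA", 14, 61, "0.958"),
    ("Asian", "9", "DA", 73, 230, "0.368"),
    ("Asian", "9", "MBA", 67, 226, "0.887"),
    ("Asian", "9", "CA", 24, 86, "0.816"),
    ("Asian", "10", "DA", 65, 204, "0.376"),
    ("Asian", "10", "MBA", 59, 220, "0.998"),
    ("Asian", "10", "CA", 15, 57, "0.848"),
    ("European", "1-10", "DA", 34, 105, "0.155"),
    ("European", "1-10", "MBA", 11, 46, "0.849"),
    ("European", "1-10", "CA", 1, 6, "0.874"),
    ("European", "11-20", "DA", 6, 11, "0.0604"),
    ("European", "11-20", "MBA", 6, 22, "0.655"),
    ("European", "11-20", "CA", 2, 2, "0.0822"),
    ("European", "1-20", "DA", 0, 1, "1"),
    ("European", "1-20", "MBA", 2, 16, "0.972"),
    ("European", "1-20", "CA", 0, 1, "0.711"),  # printed as P(X = 0); tail is 1
    ("European", "21-40", "DA", 35, 107, "0.124"),
    ("European", "21-40", "MBA", 9, 34, "0.703"),
    ("European", "21-40", "CA", 3, 4, "0.0732"),
    ("African", "1-10", "DA", 10, 60, "0.929"),
    ("African", "1-10", "MBA", 9, 47, "0.795"),
    ("African", "1-10", "CA", 0, 3, "1"),
    ("African", "11-20", "DA", 22, 99, "0.613"),
    ("African", "11-20", "MBA", 10, 44, "0.566"),
    ("African", "11-20", "CA", 0, 4, "1"),
    ("African", "1-20", "DA", 7, 34, "0.695"),
    ("African", "1-20", "MBA", 11, 53, "0.707"),
    ("African", "1-20", "CA", 0, 4, "1"),
    ("African", "21-40", "DA", 2, 2, "0.0508"),
    ("African", "21-40", "MBA", 3, 17, "0.786"),
    ("African", "21-40", "CA", 1, 1, "0.226"),
]

#: The one cell whose printed value is the k = 0 point mass, not the tail.
K0_PMF_ERRATUM = ("European", "1-20", "CA")

#: Bonferroni comparison arm in the pooled Asian replicates 1-10 sample:
#: 13 SNPs passed alpha/280, 6 of them causal.
SCAN_COUNTS = {"Asian 1-10 scan": (280, 87, 13, 6)}
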