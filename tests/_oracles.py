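"""Independent reference implementations ("oracles") used only by the tests.

These deliberately avoid the code paths of the package under test:
- Audic-Claverie tails by direct term-by-term summation of the
  posterior-predictive mass function (log-gamma arithmetic, no scipy.stats).
- Cluster detection by union-find over the pairwise gap relation
  (transitive closure), no sweep/chaining.
- A conditional-multinomial TPM envelope derived from the generator's
  source probabilities and per-base retention model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm


# ---------------------------------------------------------------- Audic-Claverie


def ac_pmf_log(yp: int, x: int, r: float) -> float:
    """log p(y'|x) with r = n2/n1, by the published closed form."""
    return (
        yp * math.log(r)
        + gammaln(x + yp + 1)
        - gammaln(x + 1)
        - gammaln(yp + 1)
        - (x + yp + 1) * math.log1p(r)
    )


def ac_lower_sum(x: int, y: int, n1: float, n2: float) -> float:
    """P(Y' <= y | x) by direct summation (y + 1 terms)."""
    r = n2 / n1
    return float(sum(math.exp(ac_pmf_log(yp, x, r)) for yp in range(y + 1)))


def ac_upper_sum(x: int, y: int, n1: float, n2: float, max_terms: int = 1_000_000) -> float:
    """P(Y' >= y | x) by forward summation from y' = y until terms vanish."""
    r = n2 / n1
    q = r / (1.0 + r)
    term = math.exp(ac_pmf_log(y, x, r))
    total = term
    yp = y
    for _ in range(max_terms):
        yp += 1
        term *= q * (x + yp) / yp  # p(y'+1)/p(y') ratio
        total += term
        # geometric tail bound once the ratio has settled below 1
        ratio = q * (x + yp + 1) / (yp + 1)
        if ratio < 1 and term * ratio / (1 - ratio) < total * 1e-16:
            break
    return float(total)


# ---------------------------------------------------------------- clusters


def clusters_by_closure(loci, max_gap: int, gap_mode: str = "interval"):
    """Connected components (size >= 2) of the pairwise within-gap relation.

    ``loci`` is a list of (id, chrom, start, end). Components are computed
    per chromosome by union-find over all pairs; returned as a set of
    frozensets of ids for order-independent comparison.
    """
    parent = {lid: lid for lid, *_ in loci}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    by_chrom: dict[str, list] = {}
    for lid, chrom, start, end in loci:
        by_chrom.setdefault(chrom, []).append((lid, start, end))
    for members in by_chrom.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ia, sa, ea = members[i]
                ib, sb, eb = members[j]
                if gap_mode == "interval":
                    gap = max(sa - eb - 1, sb - ea - 1)  # <= 0 when overlapping
                else:
                    gap = abs(sa - sb)
                if gap <= max_gap:
                    union(ia, ib)

    comps: dict[str, set] = {}
    for lid, *_ in loci:
        comps.setdefault(find(lid), set()).add(lid)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


# ---------------------------------------------------------------- TPM envelope


def retention_weights(arm_lengths, truncation_probs, error_rate):
    """Per-arm relative probability that a read is emitted AND assignable.

    A read sourced from an arm of length L is 3'-truncated by k nt with
    probability w_k and is recoverable only when its insert is error-free:
    retention(L) = sum_k w_k * (1 - e)^(L - k). Adapter/padding error effects
    are common across arms and cancel after normalisation.
    """
    out = {}
    for arm, L in arm_lengths.items():
        out[arm] = sum(
            w * (1.0 - error_rate) ** (L - k) for k, w in enumerate(truncation_probs)
        )
    return out


def multinomial_envelope_fraction(
    observed_counts, source_probs, retention, n_total, level: float = 0.99
):
    """Fraction of arms whose observed count lies in the per-arm normal
    approximation of the conditional Binomial(n_total, q_arm) interval.

    q_arm is the source probability times retention, renormalised over arms
    (conditioning on the total number of arm-assigned reads).
    """
    arms = list(observed_counts.keys())
    q = np.array([source_probs[a] * retention[a] for a in arms])
    q = q / q.sum()
    obs = np.array([observed_counts[a] for a in arms], dtype=float)
    z = norm.ppf(0.5 + level / 2.0)
    mu = n_total * q
    sd = np.sqrt(n_total * q * (1.0 - q))
    within = np.abs(obs - mu) <= z * sd + 0.5  # continuity correction
    return float(np.mean(within)), int(len(arms))
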