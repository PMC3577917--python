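"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the descriptor/algorithm
definitions with plain Python loops, deliberately sharing no code with the
package implementation it checks.
"""

import math

# Independent restatement of the eight published 3-way residue partitions.
ORACLE_GROUPS = [
    ("RKEDQN", "GASTPHY", "CVLIMFW"),      # hydrophobicity
    ("GASCTPD", "NVEQIL", "MHKFRYW"),      # normalized van der Waals volume
    ("LIFWCMVY", "PATGS", "HQRKNED"),      # polarity
    ("GASDT", "CPNVEQIL", "KMHFRYW"),      # polarizability
    ("KR", "ANCQGHILMFPSTWYV", "DE"),      # charge
    ("GQDNAHR", "KTSEC", "ILMFPWYV"),      # surface tension
    ("EALMQKRH", "VIYCWFT", "GNPSD"),      # secondary structure
    ("ALFCGIVW", "RKQEND", "MPSTHY"),      # solvent accessibility
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def oracle_188(seq: str) -> list[float]:
    """Direct-definition scan computing all 188 descriptor values."""
    L = len(seq)
    assert L >= 2
    feats = [seq.count(aa) / L for aa in ALPHABET]
    for groups in ORACLE_GROUPS:
        # content
        for g in groups:
            feats.append(sum(1 for ch in seq if ch in g) / L)
        # distribution: 1st, 25%, 50%, 75%, 100% occurrence positions
        for g in groups:
            pos = [i + 1 for i, ch in enumerate(seq) if ch in g]
            c = len(pos)
            if c == 0:
                feats.extend([0.0] * 5)
            else:
                feats.append(pos[0] / L)
                for q in (0.25, 0.50, 0.75, 1.00):
                    feats.append(pos[max(1, math.ceil(q * c)) - 1] / L)
        # bivalent frequency: unordered cross-group adjacent pairs
        counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for i in range(L - 1):
            ga = next(j for j, g in enumerate(groups) if seq[i] in g)
            gb = next(j for j, g in enumerate(groups) if seq[i + 1] in g)
            if ga != gb:
                counts[(min(ga, gb), max(ga, gb))] += 1
        feats.extend([counts[(0, 1)] / (L - 1), counts[(0, 2)] / (L - 1),
                      counts[(1, 2)] / (L - 1)])
    assert len(feats) == 188
    return feats


def oracle_levenshtein(a: str, b: str) -> int:
    """Plain full-matrix unit-cost edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


def oracle_vote(votes: list[str], priors: dict[str, int]) -> str:
    """Majority vote, ties to higher training prior then lexicographic."""
    tally: dict[str, int] = {}
    for v in votes:
        tally[v] = tally.get(v, 0) + 1
    top = max(tally.values())
    tied = sorted([l for l, c in tally.items() if c == top],
                  key=lambda l: (-priors.get(l, 0), l))
    return tied[0]


def oracle_success(member_preds: list[list[str]], y: list[str]) -> float:
    """Committee vote accuracy over per-member instance predictions."""
    priors: dict[str, int] = {}
    for lab in y:
        priors[lab] = priors.get(lab, 0) + 1
    hits = 0
    for j in range(len(y)):
        fused = oracle_vote([p[j] for p in member_preds], priors)
        hits += fused == y[j]
    return hits / len(y)


def oracle_diversity(rows: list[list[int]]) -> float:
    """Mean pairwise agreement of binary correctness rows; inf if < 2 rows."""
    p = len(rows)
    if p < 2:
        return math.inf
    m = len(rows[0])
    total, pairs = 0.0, 0
    for i in range(p):
        for j in range(i + 1, p):
            total += sum(1 for t in range(m) if rows[i][t] == rows[j][t]) / m
            pairs += 1
    return total / pairs
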