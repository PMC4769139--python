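"""Independent brute-force oracles.

Each function here re-derives an expected result by direct enumeration and
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices


def sp_runs_oracle(sequence: str) -> list[tuple[str, int, int, int]]:
    """Enumerate every S position and extend its proline run."""
    hits = []
    for i, c in enumerate(sequence):
        if c != "S":
            continue
        j = i + 1
        while j < len(sequence) and sequence[j] == "P":
            j += 1
        n = j - i - 1
        if n >= 3:
            kind = "SP3" if n == 3 else ("SP4" if n == 4 else "SP5PLUS")
            hits.append((kind, i, j, n))
    return hits


def yxy_count_oracle(sequence: str) -> int:
    count = 0
    for i in range(len(sequence)):
        if i + 2 < len(sequence) and sequence[i] == "Y" and sequence[i + 2] == "Y":
            count += 1
    return count


_HRGP6 = set("PAVSGT")


def hrgp_covered_positions_oracle(
    sequence: str, window: int = 50, threshold: float = 0.6
) -> set[int]:
    """Union of all qualifying windows, evaluated one by one."""
    n = len(sequence)
    covered: set[int] = set()
    if n < window:
        frac = sum(1 for c in sequence if c in _HRGP6) / n if n else 0.0
        return set(range(n)) if frac >= threshold else set()
    for i in range(n - window + 1):
        win = sequence[i : i + window]
        if sum(1 for c in win if c in _HRGP6) / window >= threshold:
            covered.update(range(i, i + window))
    return covered


# Kyte-Doolittle hydropathy values, transcribed independently.
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def tm_covered_positions_oracle(
    sequence: str, window: int = 19, threshold: float = 1.6
) -> set[int]:
    n = len(sequence)
    covered: set[int] = set()
    for i in range(n - window + 1):
        win = sequence[i : i + window]
        # integer tenths keep exact-threshold windows unambiguous
        total = sum(round(KD.get(c, 0.0) * 10) for c in win)
        if total > threshold * 10 * window:
            covered.update(range(i, i + window))
    return covered


def _blosum62_x() -> dict:
    b62 = substitution_matrices.load("BLOSUM62")
    aas = "ACDEFGHIKLMNPQRSTVWY"
    sub = {}
    for a in aas + "X":
        for b in aas + "X":
            if a == "X" or b == "X":
                sub[a, b] = -1
            else:
                sub[a, b] = int(b62[a, b])
    return sub


_SUB = _blosum62_x()
_NEG = float("-inf")


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Full affine-gap local-alignment DP, score only, no traceback.

    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend
            )
            F[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend
            )
            sub = _SUB.get((a[i - 1], b[j - 1]), _SUB["X", "X"])
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)
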