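"""Independent reference implementations used to cross-check the package."""

import numpy as np
from Bio import Align


def brute_force_local_score(a: str, b: str) -> int:
    """Plain full-matrix local-alignment DP (match +1, mismatch -1, -1/gap column)."""
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] - 1, H[i][j - 1] - 1)
            best = max(best, H[i][j])
    return best


def biopython_local_score(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # Biopython charges the open score on the first gap column, so a k-gap
    # costs k, matching the gapOpening=0 / gapExtension=-1 convention.
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner.score(a, b)
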