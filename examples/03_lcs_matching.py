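"""Longest-common-subsequence length, all optimal strings, and the
containment ratio used for window matching.

The dynamic program fills C[i, j] with the LCS length of the prefixes;
backtracking every optimal route from the lower-right corner recovers all
distinct LCS strings.
"""

from cgmalarm import lcs_all, lcs_length, lcs_ratio

x, y = "ffghj", "fghfgh"
print(f"lcs_length({x!r}, {y!r}) = {lcs_length(x, y)}")
print(f"all LCS strings: {sorted(lcs_all(x, y))}  (the discontinuous 'ffgh' "
      "beats the contiguous 'fgh')")

window, pattern = "ffgzzaabbccd", "gzza"
ratio = lcs_ratio(pattern, window)
print(f"pattern {pattern!r} vs window {window!r}: ratio {ratio:.2f} "
      "(1.0 = the pattern is fully contained, a match)")
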