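"""Mine frequent subsequence patterns from a toy window corpus.

Support is the fraction of corpus sequences containing a pattern as a
(not necessarily contiguous) subsequence; prefix projection enumerates
exactly the patterns at or above the minimum support.
"""

from cgmalarm import mine, support

corpus = ["gfedcbaa", "gfeedcba", "ggfedcba", "ffffgggg"]
patterns = mine(corpus, minsup=0.75)

print(f"{len(patterns)} patterns with support >= 0.75 in {len(corpus)} windows")
for p in sorted(patterns, key=lambda p: (-len(p.symbols), -p.sup))[:8]:
    print(f"  {p.symbols:<10} support {p.sup:.2f}")
print("spot check:", "'gfedcba' support =", support(corpus, "gfedcba"),
      "(3 of the 4 windows descend through every bin g..a)")
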