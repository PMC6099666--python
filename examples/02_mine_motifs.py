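"""Mining discriminative wildcard motifs by information gain and RDI.

A dataset is generated with the tripeptide KGD planted in 60% of secreted
and 5% of non-secreted proteins.  The miner enumerates every short pattern
(3-5 residues, at most one internal '-' wildcard) actually present in the
positive sequences and ranks them by RDI — the difference of the two
classes' entropy-normalised information gains — which peaks for patterns
that split one class near 50/50 while leaving the other nearly untouched.
"""

from imsp import SyntheticConfig, generate, mine_top_motifs

ds = generate(SyntheticConfig(
    n_pos=200, n_neg=200, length_range=(60, 100),
    planted_motifs=[("KGD", 0.60, 0.05)], seed=11))

motifs = mine_top_motifs(ds.positives(), ds.negatives(), k=10)

print(f"{'pattern':8s} {'in +':>5s} {'in -':>5s} {'IG+':>7s} {'IG-':>7s} {'RDI':>7s}")
for m in motifs:
    print(f"{m.pattern:8s} {m.count_pos:5d} {m.count_neg:5d} "
          f"{m.ig_pos:7.3f} {m.ig_neg:7.3f} {m.rdi:7.3f}")

print("\nThe planted KGD tops the list: present in ~60% of positives "
      "(IG+ near its 1-bit maximum)\nbut almost absent from negatives, "
      "so its RDI dwarfs the background patterns.")
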