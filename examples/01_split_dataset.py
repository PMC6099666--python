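"""Balanced train/test splitting of a labeled protein dataset.

Training takes four-fifths of the secreted proteins (floored) plus an equal
number of randomly drawn non-secreted proteins, so the classifier never sees
class imbalance; everything left over — including every surplus negative —
becomes the independent test set.
"""

from imsp import split_counts, split_dataset
from imsp.sequences import Dataset, ProteinRecord

# the six dataset sizes used in the original mammalian secretome study
ROWS = {"SPs-all": (2560, 4299), "SPs-H": (1986, 3714),
        "SPs-M": (1144, 1147), "SPs-B": (529, 1148),
        "SPs-C": (252, 492), "SPs-O": (240, 490)}

print(f"{'dataset':8s} {'all (P,N)':>14s} {'train (P,N)':>14s} {'test (P,N)':>12s}")
for name, (num_p, num_n) in ROWS.items():
    tp, tn, te_p, te_n = split_counts(num_p, num_n)
    print(f"{name:8s} {f'({num_p}, {num_n})':>14s} "
          f"{f'({tp}, {tn})':>14s} {f'({te_p}, {te_n})':>12s}")

# the splitter realizes exactly these counts on an actual dataset
recs = [ProteinRecord(f"p{i}", "MKLVW", label="SP") for i in range(240)]
recs += [ProteinRecord(f"n{i}", "MKLVW", label="nonSP") for i in range(490)]
sp = split_dataset(Dataset(recs), seed=0)
print(f"\nrealized SPs-O split: train ({sp.train.num_pos}, "
      f"{sp.train.num_neg}), test ({sp.test.num_pos}, {sp.test.num_neg})")
print("train is balanced by construction; no positive is ever discarded.")
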