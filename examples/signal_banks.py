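"""Allele-difference signal banks and the pseudo-F1 construction.

Builds the synthetic signal bank that emulates parental SNP-array
hybridizations: homozygous marker classes form two separated peaks of
opposite sign, the heterozygote class is the probe-wise mean of paired
parent draws (pseudo-F1) and sits at zero, and control probes are
centred at zero.
"""

import numpy as np

from snpbsa import make_synthetic_bank

bank = make_synthetic_bank(mu_marker=1.5, sd_marker=0.8, sd_control=0.5,
                           size=50_000, seed=0)
for label, pool in [("AA (reference parent)", bank.aa),
                    ("BB (alternate parent)", bank.bb),
                    ("AB (pseudo-F1)", bank.ab),
                    ("control probes", bank.control)]:
    print(f"{label:22s} mean {pool.mean():+.3f}  sd {pool.std():.3f}")

se = bank.ab.std() / np.sqrt(bank.ab.size)
print(f"\npseudo-F1 pool mean is {bank.ab.mean():+.4f} "
      f"({abs(bank.ab.mean())/se:.1f} standard errors from zero) — "
      "distributed about zero, as a real heterozygote would be")
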