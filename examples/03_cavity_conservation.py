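"""Score cavity-residue conservation with Schneider entropy + KS test.

Generates a toy MSA of 312 sequences with 15 planted conserved columns,
treats those columns as the wall residues of a cavity, and compares their
entropy distribution with the remainder of the protein using the
two-sample Kolmogorov–Smirnov test at α = 0.005.
"""

import numpy as np

import soltrack as st
from soltrack.evolution import ResidueMap


def main() -> None:
    msa, planted = st.make_toy_msa(n_sequences=312, n_columns=120,
                                   conserved_columns=15, seed=5)
    profile = st.entropy_profile(msa)
    print(f"MSA: {msa.n_sequences} sequences x {msa.n_columns} columns")
    print(f"mean column entropy: {np.nanmean(profile.values):.3f} "
          f"(0 = conserved, 1 = uniform)")

    # structure residue i corresponds to alignment column i (toy identity map)
    resmap = ResidueMap({r: r for r in range(1, msa.n_columns + 1)})
    cavity = [c + 1 for c in planted]
    report = st.cavity_conservation_report(profile, resmap,
                                           {"cavity_II": cavity},
                                           alpha=0.005)
    info = report["cavities"]["cavity_II"]
    ks = info["ks"]
    print(f"cavity residues: median entropy {info['median_entropy']:.3f} "
          f"vs rest {info['rest_median_entropy']:.3f}")
    print(f"KS: D = {ks.statistic:.3f}, p = {ks.pvalue:.3g}, "
          f"reject at alpha={ks.alpha}: {ks.reject}")
    # A rejected test with lower cavity median marks the cavity's residues
    # as significantly more conserved than the protein background.


if __name__ == "__main__":
    main()
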