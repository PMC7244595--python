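"""Inter-heme ferromagnetic correlations from moment bookkeeping.

The measured susceptibility of deoxy-hemoglobin, read as four independent
hemes, gives 5.46 muB per heme.  Comparing with the true single-heme
moment — 4.9 muB for a bare S = 2 ion, or 4.1 muB once the
antiferromagnetic Fe-porphyrin screening is counted — yields the average
pairwise inter-heme correlation.
"""

from hemeqmc.interheme import (
    independent_equivalent_moment,
    pair_correlation_from_moments,
)

M_expt = 5.46
for label, m_single in (("bare S=2 ion   (4.9 muB)", 4.9),
                        ("screened heme  (4.1 muB)", 4.1)):
    corr = pair_correlation_from_moments(M_expt, m_single, n_hemes=4)
    back = independent_equivalent_moment(m_single, corr, n_hemes=4)
    print(f"{label}: <M1 M2> = ({M_expt}^2 - {m_single}^2)/3 "
          f"= {corr:.2f} muB^2   (round trip -> {back:.2f} muB)")

print("\nBoth correlations are positive (ferromagnetic), and the value is")
print("larger for the screened heme moment: the stronger the local")
print("antiferromagnetic Fe-host coupling, the stronger the inter-heme")
print("ferromagnetism implied by the same molecular measurement.")
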