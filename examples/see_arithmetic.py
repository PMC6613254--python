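"""How the Standard Error of Equating is read off a bootstrap error table.

For one source score, the equating procedure is replayed on S bootstrap
resamples; the difference between each replicate's equated score and the
point estimate is an "error".  The SEE is the standard deviation of that
error.  Four canonical error distributions illustrate the scale: the last
one (SEE 0.91) is the worst case still regarded as acceptable, which is why
a weighted SEE mean below 0.91 counts as an acceptable equating.
"""

from leqate import see_from_error_distribution

distributions = {
    "error-free": {0: 1.0},
    "plausible": {-1: 0.05, 0: 0.90, 1: 0.05},
    "acceptable": {-2: 0.025, -1: 0.225, 0: 0.50, 1: 0.225, 2: 0.025},
    "worst acceptable": {-2: 0.025, -1: 0.317, 0: 0.317, 1: 0.317, 2: 0.025},
}

print(f"{'distribution':<18} {'relative frequencies':<42} SEE")
for name, freqs in distributions.items():
    pretty = ", ".join(f"{e:+d}: {f:.3f}" for e, f in sorted(freqs.items()))
    print(f"{name:<18} {pretty:<42} {see_from_error_distribution(freqs):.3f}")
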