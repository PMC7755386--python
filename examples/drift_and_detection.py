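"""Single-population drift heuristics behind the code spectrum.

Shows the three quantities that explain how codes arise: how far a common
allele drifts after a split, how likely it is to go extinct, and how likely
a rare allele is to be detected at all in a finite sample.
"""

import geovar as gv

N = 20_000  # diploid population size

# an allele at 25% drifts by about +-10 pp over 0.05 x 2N generations,
# staying 'C' in both daughters of a shallow split
dt = int(0.05 * 2 * 2 * N)
sd = gv.typical_frequency_change(0.25, 0.05 * 2 * N, N)
print(f"typical drift of a 25% allele over 0.05 x 2N generations: "
      f"+-{100 * sd:.1f} pp -> likely interval "
      f"({25 - 100 * sd:.0f}%, {25 + 100 * sd:.0f}%)")

# extinction probability rises with time toward 1 - f0 (small-N exact path)
print("\nextinction probability of a 25% allele (N = 100, exact matrix):")
for t in (10, 100, 400, 1600, 6000):
    p = gv.extinction_probability(0.25, t, 100, method="matrix")
    print(f"  t = {t:>5} generations: {p:.3f}")
print("  long-run limit 1 - f0 = 0.750")

# surviving new mutations grow roughly linearly in frequency
print("\nconditional mean frequency of a new mutation (N = 100):")
for t in (10, 20, 40):
    m = gv.conditional_mean_frequency(1 / 200, t, 100, method="matrix")
    print(f"  t = {t:>3}: E[f | survival] = {m:.4f}  (envelope t/2N = {t / 200:.3f})")

# detection power: why 'u' does not mean absent from the population
print("\nprobability of detecting an allele at least once in 404 diploids:")
for f in (0.0005, 0.002, 0.01):
    print(f"  population frequency {100 * f:.2f}%: "
          f"power {gv.detection_power(f, 404):.2f}")
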