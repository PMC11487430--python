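"""Control analyses and performance statistics.

Three desk-scale checks that frame any speller result: the chance level of
random decoding on a 6x6 matrix, the Quade test comparing eight published
decoders across eight subjects, and the Wolpaw information transfer rate
implied by a given accuracy and flash timing.
"""

from p300wave import (
    information_transfer_rate,
    letter_rate_table,
    quade_test,
    selection_time_s,
    simulate_chance_level,
    wolpaw_bits_per_selection,
)

acc = simulate_chance_level(n_letters=10000, seed=0)
print(f"random-score decoding over 10,000 letters: {100 * acc:.2f}% "
      f"(chance = 1/36 = {100 / 36:.2f}%)")

table = letter_rate_table()
res = quade_test(table.to_numpy())
print(f"\nQuade test across {table.shape[0]} subjects x {table.shape[1]} methods: "
      f"F({res.df_num}, {res.df_den}) = {res.statistic:.3f}, p = {res.pvalue:.3f}")
print("no significant difference between the eight decoders on this benchmark")

print("\ninformation transfer rate (36-choice speller):")
for p, n_reps in [(0.9, 5), (0.9, 10), (1.0, 10)]:
    t = selection_time_s(n_reps)
    bits = wolpaw_bits_per_selection(p, 36)
    bps = information_transfer_rate(p, 36, t)
    print(f"  accuracy {p:.0%} at {n_reps:2d} intensifications "
          f"({t:4.1f} s/letter): {bits:.2f} bits/selection = {bps:.3f} bps")
print("fewer repetitions spell faster but risk accuracy: the ITR trade-off")
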