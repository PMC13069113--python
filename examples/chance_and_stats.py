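"""Study-level statistics from the packaged per-subject tables.

Reproduces the chance-level bounds for random 3-class classification,
the offline/online accuracy summaries across the 20 subjects, and the
Welch t-test of the online accuracies against a random-classification
reference distribution.
"""

from vibci import (
    accuracy_change,
    chance_upper_bound,
    count_above,
    load_accuracy_table,
    summarize_accuracies,
    welch_t,
)

print("adjusted-Wald upper bounds on random 3-class accuracy:")
for n_per_class, alpha in [(160, 0.01), (160, 0.05), (20, 0.01)]:
    b = chance_upper_bound(n_per_class, 3, alpha)
    print(f"  {n_per_class:4d} trials/class, {100 * (1 - alpha):.0f}% level"
          f" : {b.bound:5.2f} %")

table = load_accuracy_table("per_subject")
offline_mean, offline_sd = summarize_accuracies(table.offline_mean_pct)
online_mean, online_sd = summarize_accuracies(table.online_pct)
print(f"\noffline mean accuracy : {offline_mean:.2f} % (population sd "
      f"{offline_sd:.2f}), {count_above(table.offline_mean_pct, 39.0)}/20 "
      "subjects above the 39.0% bound")
print(f"online mean accuracy  : {online_mean:.2f} % "
      f"(population sd {online_sd:.2f})")

# Reference: random 3-class classification with 20 trials/class has
# mean 33.33% and sd 26.05 across repetitions.
res = welch_t(online_mean, online_sd, len(table), 100 / 3, 26.05, 20)
print(f"Welch t vs random     : t = {res.t:.2f}, df = {res.df:.1f}")

check = load_accuracy_table("frequency_check").set_index("subject")
d17 = accuracy_change(check.loc[17, "primary_mean_pct"],
                      check.loc[17, "secondary_mean_pct"])
print(f"\ns.17 primary - secondary couple accuracy: {d17:+.2f} points")
# A positive change means the peak-score selection picked the better
# frequency couple for that subject.
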