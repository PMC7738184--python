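"""Cone-gain color constancy of the first on-glasses settings, day by day.

Renders the cohort's settings to physical spectra, converts them to relative
cone gain k = L/M (through the glasses for glasses-on settings), and locates
each day's first on-glasses setting between no compensation (baseline k) and
perfect constancy (baseline pixels viewed through the glasses).
"""

from chromadapt import (
    CohortParams,
    daily_constancy,
    default_monitor,
    simulate_cohort,
    summarize_tests,
    synth_red_glasses,
)

records = simulate_cohort(CohortParams(seed=1))
summaries = summarize_tests(records)
table = daily_constancy(summaries, default_monitor(), synth_red_glasses())

print(table[["day", "k_baseline", "k_setting", "k_perfect", "percent"]]
      .round(3).to_string(index=False))
print("\nk_baseline: gain at the no-glasses baseline setting;")
print("k_perfect:  gain of those same pixels seen through the glasses;")
print("percent:    how far the day's first on-glasses setting moved from")
print("            baseline toward perfect constancy. It grows across days")
print("            as the synthetic observers learn to switch modes.")
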