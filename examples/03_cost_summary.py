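"""Arm-by-component cost table with BCa bootstrap confidence intervals.

Mean per-participant costs over three years are summarised per arm for
participants with complete follow-up, with bias-corrected and accelerated
(BCa) bootstrap 95% CIs and a global Kruskal–Wallis test per component.
Intervention costs separate the arms even when underlying resource use
does not.
"""

from mapt_cea import (TrialConfig, apply_missingness, cost_panel_for,
                      generate_trial, summarize_costs)

config = TrialConfig(n_per_arm=380, random_seed=7)
dataset = apply_missingness(generate_trial(config), config)
panel = cost_panel_for(dataset)
summary = summarize_costs(panel, dataset, B=1000, seed=1)

print(f"complete cases per arm:\n{summary.n_complete.to_string()}\n")
rows = summary.table.set_index(["component", "arm"])
for component in ("total_without_intervention", "total_with_intervention"):
    kw_p = summary.tests.set_index("component").loc[component, "kw_p"]
    print(f"{component}  (Kruskal-Wallis p = {kw_p:.3f})")
    for arm in dataset.arms:
        r = rows.loc[(component, arm)]
        print(f"  {arm:>8}: €{r.cost_mean:7.0f}  "
              f"[{r.cost_lo:7.0f}; {r.cost_hi:7.0f}]")
print("\nWithout intervention the arms are exchangeable; including the "
      "intervention cost separates them, as the rank test shows.")
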