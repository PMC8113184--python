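"""Render the per-case stacked ACS bar report for a simulated cohort.

One bar per case, ordered by light-microscopy VAS then AS; the four
coloured segments are the per-category ACS values (their stack height is
the case AS), annotated with VAS and the TRI / myophagocytosis / nuclear
inclusion flags.
"""

from pathlib import Path

from capscore import default_cohort_config, plot_acs_report, simulate_cohort

result = simulate_cohort(default_cohort_config(master_seed=1))
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "acs_report.png"
plot_acs_report(result.cases, str(path))
print(f"wrote {path} with {len(result.cases)} case bars")
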