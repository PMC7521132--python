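"""Run a small synthetic study end to end and test brain-behavior coupling.

A cohort is drawn with a Gaussian copula linking each subject's expectancy
gain g (how much larger their N1-P2 is to unexpected beats) and tapping
concentration kappa, at population Spearman rho = 0.6. Every subject's
session is simulated, analyzed, and summarized; the study statistic is the
Spearman correlation between the timing response index (TRI) and tapping
vector strength (VS). At this reduced cohort size the estimate is noisy
but the recovered correlation is typically positive and sizeable.
"""

from oddbeat.study import StudyConfig, run_study

cfg = StudyConfig(n_subjects=12, rho_pop=0.6, seed=3, rate=500.0,
                  tapping_duration=60.0, top_bottom_k=4)
res = run_study(cfg, out_dir="study_report")

sp = res.stat_results["spearman_tri_mean50_vs"]
tt = res.stat_results["paired_t_deviant_gt_standard"]
dg = res.stat_results["vs_diagnostics"]

print(res.table[["subject", "gain", "kappa", "vs", "tri_mean50"]].round(3).to_string(index=False))
print(f"\nSpearman(TRI, VS): rho={sp['statistic']:.3f}, p={sp['p']:.4f} (n={sp['n']})")
print(f"deviant > standard N1-P2: t={tt['statistic']:.2f}, df={tt['df']}, p={tt['p']:.2g}")
print(f"VS diagnostics: skewness={dg['skewness']:.2f}, "
      f"Lilliefors p={dg['lilliefors_p']:.3f}")
print("report written to study_report/")
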