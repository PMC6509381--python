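"""Fit and tune the maximum-entropy niche model.

Thins the occurrences, extracts predictors, tunes the regularization
multiplier and feature classes by AICc, then cross-validates the winner and
derives the three cloglog thresholds and their TSS-weighted average.
"""

import coastniche as cn

stack = cn.make_grid(cn.GridSpec(100, 200), seed=42)
truth = cn.default_true_model(stack)
occ = cn.thin_occurrences(cn.sample_occurrences(stack, truth, 300, seed=1),
                          cell_size=1.0)
print(f"{len(occ)} presences after one-per-cell thinning")

presence = cn.extract_predictors(occ, stack, label=1).data
background = cn.extract_predictors(cn.sample_background(stack, 10_000, seed=2),
                                   stack, label=0).data
categorical = {"Drainage", "Tclass"}

tuning = cn.tune(presence, background, rm_list=[1, 2, 3, 4],
                 fc_list=["L", "LQ", "LQH"], categorical=categorical)
print(tuning.table.sort_values("aicc").head(4).to_string(index=False))
print(f"selected RM={tuning.best_rm:g}, FC={tuning.best_fc} "
      f"(smallest AICc wins; complexity is penalized)")

cfg = cn.MaxentConfig(rm=tuning.best_rm, fc=tuning.best_fc)
cv = cn.cross_validate(presence, background, cfg, k=10, seed=3,
                       categorical=categorical)
print(f"10-fold CV: mean AUC {cv.mean_auc:.3f}, mean TSS {cv.mean_tss:.3f} "
      f"(AUC > 0.9 is considered good; TSS > 0.6 good)")

model = tuning.best_model
ts = cn.thresholds(model.predict_cloglog(presence),
                   model.predict_cloglog(background))
print(f"thresholds: MTSS {ts.mtss:.4f}, PTSS {ts.ptss:.4f}, ETSS {ts.etss:.4f}")
print(f"TSS-weighted average threshold: {ts.weighted:.4f} "
      f"(used to binarize suitability into habitat maps)")
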