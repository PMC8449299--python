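"""Validate EHR-derived collaboration likelihoods against expert ratings.

Twelve role-pair relationships (six labeled high-likelihood by the network
analysis, six low) were each rated 1-5 by a blinded expert panel. The
discrimination model regresses the Likert score on the 0/1 label:
alpha is the low-group mean, alpha + beta the high-group mean, and the
F-test of beta != 0 asks whether experts can tell the groups apart.
"""

from ehrcollab import datasets, survey

scores = datasets.example_survey_scores()
print(survey.summarize_survey(
    scores.rename(columns={"relationship": "rel"})
)[["relationship_id", "label", "mean_likert"]].to_string(index=False))

fit = survey.fit_likelihood_model(scores)
print(f"\nalpha (low-group mean Likert) = {fit.alpha:.2f}")
print(f"alpha + beta (high-group mean) = {fit.alpha + fit.beta:.2f}")
print(f"beta (high - low difference)   = {fit.beta:.2f}")
print(f"F = {fit.f_stat:.2f} (= t^2 = {fit.t_stat**2:.2f}), p = {fit.p_value:.3f}")
print("\nExperts rate the high-likelihood relationships ~0.9 Likert points "
      "above the low ones; with only 12 panel-mean observations the "
      "difference sits at the edge of significance (response-level data "
      "sharpens it).")
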