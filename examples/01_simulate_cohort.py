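"""Generate the default six-group synthetic cohort and inspect its truth.

The design mirrors the study conditions: 88 preadolescent controls (PAC),
94/61 preadolescent GHD/ISS (PAG/PAI), 40 adolescent controls (ADC) and
43/19 adolescent GHD/ISS (ADG/ADI), with per-group age/sex models and
planted fold changes on the intended biomarker panels.
"""

import ssmetab as sm

design = sm.CohortDesign(seed=1)
conc, clinical, manifest = sm.generate_cohort(design)

print("samples x metabolites:", conc.shape)
print("group sizes:", clinical["group"].value_counts().to_dict())
print("\nfirst samples:")
print(conc.iloc[:3, :4].round(3))
print("\nplanted biomarkers for PAG vs PAC "
      f"({len(manifest.planted[('PAG', 'PAC')])} metabolites):")
print(sorted(manifest.planted[("PAG", "PAC")]))
# Every downstream stage is scored against this manifest: the planted sets
# are the ground truth the screen is expected to recover.
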