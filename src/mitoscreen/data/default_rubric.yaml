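# Default pathogenicity rubric — a documented reconstruction of a weighted
# clinical scoring scheme for mtDNA protein-coding variants.  The original
# point values are not public in a form this package can restate, so every
# constant here is an editable package default, not a citation.
#
# Evidence keys resolve into an EvidenceBundle:
#   nucleotide_ci / aa_ci          conservation indices (percent, computed)
#   external_frequency             database carrier count (user-supplied)
#   predictor_scores.<name>        external predictor probabilities in [0,1]
#   disease_report_flags.<name>    booleans from the clinical literature
#
# Bin semantics: numeric bins are [min, max) with a missing bound open; an
# "unknown: true" bin catches absent evidence; "equals" matches exactly.
# Maximum attainable total: 19 points.  Tier cuts: <6 Neutral/polymorphic,
# 6-10 Possibly, 11-15 Probably, >=16 Definitely pathogenic.

criteria:
  - name: nucleotide_conservation
    key: nucleotide_ci
    domain: [0, 100]
    bins:
      - {max: 50, points: 0}
      - {min: 50, max: 80, points: 1}
      - {min: 80, points: 2}
      - {unknown: true, points: 0}
  - name: amino_acid_conservation
    key: aa_ci
    domain: [0, 100]
    bins:
      - {max: 50, points: 0}
      - {min: 50, max: 80, points: 1}
      - {min: 80, points: 2}
      - {unknown: true, points: 0}
  - name: database_frequency
    key: external_frequency
    domain: count
    bins:
      - {min: 0, max: 1, points: 3}     # absent from the population database
      - {min: 1, max: 10, points: 2}
      - {min: 10, max: 100, points: 1}
      - {min: 100, points: 0}           # common polymorphism
      - {unknown: true, points: 1}
  - name: predictor_polyphen2
    key: predictor_scores.polyphen2
    domain: [0, 1]
    bins:
      - {max: 0.5, points: 0}
      - {min: 0.5, max: 0.85, points: 1}
      - {min: 0.85, points: 2}
      - {unknown: true, points: 0}
  - name: predictor_mutpred
    key: predictor_scores.mutpred
    domain: [0, 1]
    bins:
      - {max: 0.5, points: 0}
      - {min: 0.5, max: 0.75, points: 1}
      - {min: 0.75, points: 2}
      - {unknown: true, points: 0}
  - name: independent_reports
    key: disease_report_flags.independent_reports
    domain: boolean
    bins:
      - {equals: true, points: 2}
      - {equals: false, points: 0}
      - {unknown: true, points: 0}
  - name: heteroplasmy
    key: disease_report_flags.heteroplasmy
    domain: boolean
    bins:
      - {equals: true, points: 2}
      - {equals: false, points: 0}
      - {unknown: true, points: 0}
  - name: segregation
    key: disease_report_flags.segregation
    domain: boolean
    bins:
      - {equals: true, points: 2}
      - {equals: false, points: 0}
      - {unknown: true, points: 0}
  - name: biochemistry
    key: disease_report_flags.biochemistry
    domain: boolean
    bins:
      - {equals: true, points: 2}
      - {equals: false, points: 0}
      - {unknown: true, points: 0}

tier_thresholds: [6, 11, 16]
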