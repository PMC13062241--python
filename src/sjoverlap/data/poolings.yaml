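# Named study groupings for the familial-aggregation meta-analyses.
#
# Each grouping lists the exact studies entering the pooled estimate.  National
# cohorts that overlap (Sweden, Taiwan) are de-duplicated by keeping the study
# with the larger proband count, which is why e.g. only one of the two Taiwanese
# SLE registry studies enters the SLE pooling and the Taiwanese SSc row from the
# 2015 multi-disease registry is dropped in favour of the dedicated 2016 study.
# The IIM rows carry log relative risks recomputed from the RR column (the
# printed logRR for one row is inconsistent with its RR).
poolings:
  sjd_to_sjd:
    description: Concordant Sjogren's disease in first-degree relatives of SjD probands
    proband_disease: SjD
    fdr_disease: SjD
    relative_class: first_degree
    studies: [Eaton 2007, Kuo 2015a, Thomsen 2020a]
  sjd_to_ad:
    description: Any other autoimmune disease in first-degree relatives of SjD probands
    proband_disease: SjD
    fdr_disease: AD
    relative_class: first_degree
    studies: [Anaya 2006, Priori 2007, Ben-Eli 2019, Thomsen 2020a]
  ra_to_sjd:
    description: SjD in first-degree relatives of rheumatoid-arthritis probands
    proband_disease: RA
    fdr_disease: SjD
    relative_class: first_degree
    studies: [Kuo 2015a, Thomsen 2020a]
  sle_to_sjd:
    description: SjD in first-degree relatives of systemic-lupus probands
    proband_disease: SLE
    fdr_disease: SjD
    relative_class: first_degree
    studies: [Bengtsson 2002, Kuo 2015a, Thomsen 2020a]
  ssc_to_sjd:
    description: SjD in first-degree relatives of systemic-sclerosis probands
    proband_disease: SSc
    fdr_disease: SjD
    relative_class: first_degree
    studies: [Kuo 2016, Thomsen 2020a]
  iim_to_sjd:
    description: SjD in first-degree relatives of inflammatory-myopathy probands
    proband_disease: IIM
    fdr_disease: SjD
    relative_class: first_degree
    studies: [Ginn 1998, Kuo 2015a, Thomsen 2020a]
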