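# Default variant-filter settings for FFPE amplicon panels.
# Thresholds follow the conventional reporting rules for this assay class:
# phred strictly above 30, coverage of at least 100 reads, a 5% reporting
# floor on VAF with manual-review band up to 20%.
filter:
  min_phred: 30.0          # exclusive: quality must be > min_phred
  min_coverage: 100        # inclusive: coverage >= min_coverage passes
  vaf_reject_below: 0.05   # VAF < 5% rejected
  vaf_auto_accept_at: 0.20 # VAF >= 20% auto-accepted; [5%,20%) -> review band
  primer_proximity_bp: 5   # insert-edge exclusion window, bp
  min_overlap_support_reads: 1
  min_overlap_coverage: 20 # reads needed in the second amplicon to judge concordance
  blacklist: default       # "default" = packaged list; or a path; or null
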