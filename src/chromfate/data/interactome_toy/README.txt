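Synthetic 12-protein x 2-replicate AP-MS toy dataset (hand-constructed, not
derived from any experiment). Each replicate total is exactly 100 unique
peptides so every fraction and fold ratio is hand-checkable:
  P01 candidate via rep1 (10/100 vs 2/100, ratio 5)
  P02 candidate via rep2 (8/100 vs 2/100, ratio 4)
  P03 never: 1 peptide in rep1 (prefiltered), ratio 1 in rep2
  P04 candidate via rep1 zero-control path (0.02 / (0.5/100) = 4)
  P05 never: 0 peptides in rep1, ratio 1 in rep2
  P06 never: ratio 1 in both
  P07 candidate via rep1 (ratio 4)
  P08 candidate via rep1 at the exact two-fold boundary (4/100 vs 2/100)
  P09 candidate via rep2 at the exact two-fold boundary (2/100 vs 1/100)
  P10 never: depleted in rep1, ratio 1 in rep2
  BG1/BG2 on the background list, removed.
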