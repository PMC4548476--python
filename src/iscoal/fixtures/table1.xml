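<k69data name="table1">
  <haplotype count="2">1000</haplotype>
  <haplotype count="1">1111</haplotype>
  <haplotype count="1">1100</haplotype>
  <haplotype count="1">0000</haplotype>
</k69data>
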