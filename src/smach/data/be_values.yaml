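# Published biomonitoring-equivalent (BE/HBM) guideline values in urine, µg/L,
# with the metabolite basis each value is expressed on.  The DEHP value is on
# the sum of its four oxidative/hydrolytic metabolites; DINP on the carboxy
# metabolite.
version: 1
guidelines:
  dbp:
    be_ug_per_l: 2700
    basis: [mbp]
  bbzp:
    be_ug_per_l: 3800
    basis: [mbzp]
  dehp:
    be_ug_per_l: 400
    basis: [mehp, mehhp, meohp, mecpp]
  dinp:
    be_ug_per_l: 390
    basis: [mciop]
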