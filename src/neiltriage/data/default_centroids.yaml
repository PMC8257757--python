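# Reference centroids of the three metastable lesion-recognition-loop
# conformations in (d242, d244) descriptor space, in angstroms.
#
# These are operational values consistent with the crystallographic
# conformers (242-in: residue-242 terminal N hydrogen-bonded ~3 A to the
# flipped base with Tyr244 swung out; 244-in: Tyr244 stacked ~3.6 A on the
# base with residue 242 displaced; apo: the whole loop rotated away, both
# contacts >9 A).  No published numerical centroid coordinates exist for
# the three zones; override freely for a specific ensemble.
apo:
  d242: 12.0
  d244: 10.0
in242:
  d242: 3.0
  d244: 8.0
in244:
  d242: 8.0
  d244: 3.5
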