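# Deposited coordinates (user-supplied)

The structural validation test
(`tests/test_acceptance.py::test_structural_measurements_on_deposited_coordinates`)
measures the activated-state 242–base contact (~3.0 Å), the apo-loop
displacement (>9 Å) and the ~40° hinge rotation directly from
experimentally deposited crystal structures. Those coordinate files are
not redistributed with this package and no network access is assumed, so
the test fails with an explanatory message until you supply them:

* `5ity.pdb` — hNEIL1(R242) bound to thymine-glycol-containing duplex DNA
* `5itq.pdb` — the free (apo) enzyme

Download both entries from the Protein Data Bank in PDB format and place
them in this directory under the names above. All other tests and the
acceptance script are self-contained.
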