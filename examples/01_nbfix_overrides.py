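"""Emit the CHARMM NBFIX block that keeps probes out of the bilayer.

The repulsion protocol overrides the Lennard-Jones interaction between the
probe's central carbon type and the lipid acyl-chain methylene type CTL2:
well depth collapsed to 0.01 kcal/mol, pair minimum-energy distance pushed
to 7 Å.  Appending this block to a CHARMM parameter stream is the entire
force-field modification.
"""

from pmdmembrane import build_overrides, emit_nbfix_stream, parse_nbfix_stream

# CG311 is the CGenFF type of the isopropanol central carbon; substitute
# your probe's actual type label
overrides = build_overrides("CG311", ["CTL2"])
stream = emit_nbfix_stream(overrides)

print(stream)
print("parsed back:", parse_nbfix_stream(stream))
print("The -0.010000 field is the well depth (negative by CHARMM "
      "convention, i.e. 0.01 kcal/mol of attraction left); 7.000000 is the "
      "pair minimum-energy inter-particle distance in Å — large enough that "
      "the probe cannot nestle between lipid tails.")
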