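"""How design speed controls the agreement of the two PPI constructions.

Draws 1000 Gaussian neuronal series, builds the PPI term by
convolve-then-multiply and by multiply-then-convolve for an event-related
design and block designs of increasing cycle length, and prints the
distribution of their Pearson correlations per design.  High values mean
the (simpler) non-deconvolution construction is a good stand-in for the
neuronal-level interaction; block designs of 40 s cycles and slower sit
above ~0.9, the event design below 0.5.
"""

from ppikit import SimGrid, run_simulation

result = run_simulation(SimGrid(n_sim=1000, seed=0))
print(result.summary.round(3))
print(
    "\nMean r rises with cycle length: slow designs make the two PPI terms"
    "\nnearly interchangeable, fast (event) designs do not."
)
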