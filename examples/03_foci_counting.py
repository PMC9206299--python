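"""Count gammaH2AX foci per nucleus in a synthetic high-content field.

Builds a two-channel field with five disc-shaped nuclei, three planted
foci each, a planar illumination gradient, and Poisson counting noise;
then runs background correction, nucleus segmentation with the
morphology/intensity acceptance windows, and box-method spot detection.
"""

from synletscreen import simulate
from synletscreen.imaging import foci_statistics, quantify_field

amp = simulate.poisson_amplitude_for_snr(8.0, 650.0)
image, truth = simulate.gen_foci_image(
    seed=3, n_nuclei=5, foci_per_nucleus=3, background_slope=150.0,
    foci_amplitude=amp, noise="poisson", condition="combination",
)
table = quantify_field(image)
print(table.to_string(index=False))
print(foci_statistics(table).to_string(index=False))
print(
    f"\nGround truth planted 3 foci in each of {len(truth['nuclei'])} nuclei. "
    "Mean foci per cell is the DNA-damage readout; in the real assay a two- to\n"
    "threefold increase over vehicle indicates accumulating double-strand breaks."
)
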