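"""Show how the filter parameters adapt to the pixel resolution.

The Gaussian kernel radius of the edge detector and the maximum-filter
radius both scale with the physical pixel size; everything else comes from
the magnification preset.
"""

from brightseg import default_config, select_parameters
from brightseg.pipeline import config_to_text

for nm in (110, 200, 300, 400):
    gaussian, max_radius = select_parameters(nm)
    print(f"{nm:4d} nm/pixel -> gaussian kernel radius {gaussian}, maximum filter radius {max_radius}")

print("\nhigh-magnification preset at 110 nm/pixel:")
print(config_to_text(default_config(110, "high_mag")))
print("low-magnification preset at 400 nm/pixel:")
print(config_to_text(default_config(400, "low_mag")))
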