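"""Score sites with the Niche Margin Index against a niche envelope.

NMI = (signed distance to the niche margin) / (depth of the deepest interior
point): 1 at the niche's climatic core, 0 on the margin, negative outside
(below -1 means farther out than the niche is deep).
"""

import numpy as np

from nichemargin import NicheEnvelope, max_inner_distance, nmi
from shapely.geometry import MultiPolygon, Polygon

# a simple elliptical niche envelope in environmental space
theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
ring = np.column_stack([2 * np.cos(theta), np.sin(theta)])
envelope = NicheEnvelope(method="kde", level=0.99, geometry=MultiPolygon([Polygon(ring)]))

print(f"niche depth (standardization denominator): {max_inner_distance(envelope):.3f}")

sites = np.array([
    [0.0, 0.0],   # niche center
    [1.0, 0.0],   # halfway to the margin along the long axis
    [2.0, 0.0],   # exactly on the margin
    [3.0, 0.0],   # outside
    [0.0, -2.5],  # far outside along the short axis
])
for site, r in zip(sites, nmi(sites, envelope)):
    where = "inside" if r.inside else "outside"
    print(f"site ({site[0]:+.1f}, {site[1]:+.1f}): distance {r.distance:+.3f}, "
          f"NMI {r.nmi:+.3f} ({where})")
# Positive NMI = climate matching within the native niche (innerness);
# negative NMI quantifies how far beyond the margin a site lies (outerness),
# information that suitability indices floored at zero cannot express.
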