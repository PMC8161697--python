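"""Depth-grid and circle constants shared by every stage.

Depth convention (used everywhere in the package): the volume is sampled on
a 3.87 µm axial grid below the ILM. Slab ``k`` spans
``[k * 3.87, (k + 1) * 3.87)`` µm and its *reported* depth is its anterior
edge ``k * 3.87`` µm. Fifty slabs cover 0–193.5 µm.
"""

#: Axial sample spacing / slab thickness, µm.
SLAB_UM: float = 3.87

#: Number of single-sample enface slabs (0–193.5 µm below the ILM).
N_SLABS: int = 50

#: Deepest depth covered by the stack, µm (= N_SLABS * SLAB_UM).
MAX_DEPTH_UM: float = 193.5

#: Radius of the peripapillary measurement circle, µm (3.5 mm diameter).
CIRCLE_RADIUS_UM: float = 1750.0


def slab_depth_um(k: int) -> float:
    """Reported depth (anterior edge) of slab ``k`` in µm below the ILM."""
    return k * SLAB_UM
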