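"""Canonical names and orderings shared across the pipeline.

Column and condition orderings are fixed here once; every matrix the package
builds uses them, so serialized artifacts are interoperable.
"""

#: The six functional habenula subtypes, in canonical column order.
SUBTYPES = (
    "D-ON-Tonic",
    "D-OFF-Tonic",
    "D-OFF-Phasic",
    "V-ON-Tonic",
    "V-OFF-Tonic",
    "V-OFF-Phasic",
)

DORSAL_SUBTYPES = ("D-ON-Tonic", "D-OFF-Tonic", "D-OFF-Phasic")
VENTRAL_SUBTYPES = ("V-ON-Tonic", "V-OFF-Tonic", "V-OFF-Phasic")

#: Experimental conditions in canonical row-block order.
CONDITIONS = ("unablated", "D-ON", "V-ON", "V-OFF")

#: Which subtypes each ablation experiment removes.
ABLATION_MAP = {
    "unablated": (),
    "D-ON": ("D-ON-Tonic",),
    "V-ON": ("V-ON-Tonic",),
    "V-OFF": ("V-OFF-Tonic", "V-OFF-Phasic"),
    "D-OFF": ("D-OFF-Tonic", "D-OFF-Phasic"),  # counterfactual, never trained on
}

REGIONS = ("dorsal", "ventral", "raphe")


def region_of(subtype: str) -> str:
    if subtype in DORSAL_SUBTYPES:
        return "dorsal"
    if subtype in VENTRAL_SUBTYPES:
        return "ventral"
    raise ValueError(f"unknown subtype: {subtype!r}")
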