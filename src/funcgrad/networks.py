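"""Canonical resting-state network set.

Seven large-scale cortical networks in a fixed order: visual (VN),
sensorimotor (SMN), dorsal attention (DAN), ventral attention (VAN),
limbic (LN), frontoparietal (FPN) and default mode (DMN). The order is
the tie-break order wherever a deterministic choice between networks is
needed (e.g. majority-vote assignment).
"""

NETWORKS: tuple[str, ...] = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

N_NETWORKS: int = len(NETWORKS)

NETWORK_INDEX: dict[str, int] = {name: i for i, name in enumerate(NETWORKS)}


def validate_network(name: str) -> str:
    """Return *name* if it is one of the seven canonical networks, else raise."""
    if name not in NETWORK_INDEX:
        raise ValueError(
            f"unknown network {name!r}; expected one of {', '.join(NETWORKS)}"
        )
    return name
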