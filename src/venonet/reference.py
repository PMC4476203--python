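"""Access to the bundled synthetic reference anatomy.

The packaged anatomy table is a synthetic reconstruction of the
cerebrospinal venous network for a supine subject: the vessel set and
connectivity follow the standard anatomical description (dural sinuses and
deep Galenic system intracranially; jugular, vertebral and vertebral-plexus
routes in the neck; azygos, thoracic/lumbar plexus and caval axis below the
heart), while equivalent diameters and lengths are plausible
literature-range values calibrated once against supine venous physiology.
Two nodes are held at zero pressure: the subclavian vein (large calibre,
negligible resistance) and the right atrium (negligible atrial pressure);
the zero right-atrial pressure decouples the network into an upper
(cerebral + upper spinal) and a lower (cardiac + lower spinal) system.
"""

from __future__ import annotations

from importlib import resources

from .anatomy import NetworkTopology, load_anatomy_table

__all__ = [
    "reference_topology",
    "reference_paths",
    "IJV_IDS",
    "VV_IDS",
    "PROXIMAL_AZYGOS_IDS",
    "GALENIC_CONFLUENCE_NODE",
    "SSS_POSTERIOR_NODE",
    "IJV_UPSTREAM_NODES",
]

#: the two internal jugular veins
IJV_IDS = ("IJV_l", "IJV_r")

#: all vertebral-vein segments, both sides
VV_IDS = tuple(f"VV_{s}{i}" for s in ("l", "r") for i in range(1, 7))

#: the four proximal azygos segments (numbered from the cavoatrial end)
PROXIMAL_AZYGOS_IDS = ("AZ1", "AZ2", "AZ3", "AZ4")

#: node where the basal (Rosenthal) and internal cerebral veins join the
#: great vein of Galen -- the intracranial pressure probe
GALENIC_CONFLUENCE_NODE = "galenic_confluence"

#: downstream (posterior) end of the superior sagittal sinus
SSS_POSTERIOR_NODE = "torcular"

#: cranial end of each internal jugular vein (the jugular bulb)
IJV_UPSTREAM_NODES = {"IJV_l": "jugular_bulb_l", "IJV_r": "jugular_bulb_r"}


def reference_paths() -> tuple[str, str]:
    """Filesystem paths of the bundled anatomy CSV and boundary config."""
    data = resources.files("venonet") / "data"
    return (
        str(data / "anatomy_synthetic_reference.csv"),
        str(data / "config_synthetic_reference.yaml"),
    )


def reference_topology() -> NetworkTopology:
    """Load and validate the bundled synthetic reference anatomy."""
    anatomy, config = reference_paths()
    return load_anatomy_table(anatomy, config)
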