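"""Bundled brain-node fixture: AAL-116 region labels with MNI centroids.

The 116 labels follow the standard automated-anatomical-labelling (AAL)
parcellation naming. The centroid coordinates shipped in
``data/aal116_nodes_synthetic.tsv`` are approximate synthetic stand-ins used
only to position nodes for g-map export — they are not the atlas' exact
centres of mass and must not be used for spatial analysis.

Node *roles* (cortical / subcortical / cerebellar) are assigned from the
label text: cerebellar regions carry a ``Cerebelum``/``Vermis`` prefix,
subcortical regions are the deep grey-matter structures (caudate, putamen,
pallidum, thalamus, hippocampus, amygdala), and everything else is cortical.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"
CEREBELLAR = "cerebellar"

_SUBCORTICAL_PREFIXES = (
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Hippocampus",
    "Amygdala",
)
_CEREBELLAR_PREFIXES = ("Cerebelum", "Vermis")


def node_role(label: str) -> str:
    """Role of a node inferred from its AAL label."""
    if label.startswith(_CEREBELLAR_PREFIXES):
        return CEREBELLAR
    if label.startswith(_SUBCORTICAL_PREFIXES):
        return SUBCORTICAL
    return CORTICAL


def load_node_fixture() -> pd.DataFrame:
    """Load the bundled 116-node fixture.

    Returns
    -------
    DataFrame with columns ``label``, ``mni_x``, ``mni_y``, ``mni_z``,
    ``role``, in atlas order.
    """
    ref = resources.files("phconn").joinpath("data/aal116_nodes_synthetic.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["role"] = [node_role(lbl) for lbl in df["label"]]
    return df


def node_roles(labels) -> list[str]:
    """Roles for an arbitrary ordered list of node labels."""
    return [node_role(str(lbl)) for lbl in labels]
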