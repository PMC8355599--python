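"""Subnetwork extraction: TF-centered ego networks and gene-list restriction."""

from __future__ import annotations

import warnings
from typing import Iterable

from .model import RegulatoryNetwork


def ego_out(net: RegulatoryNetwork, center: str) -> RegulatoryNetwork:
    """Induced subgraph on a node plus the targets of its outgoing edges.

    The node set is {center} plus every node the center regulates; the edge
    set is *all* edges of ``net`` among those nodes, not just the star —
    regulation between the center's targets (and back into the center) is
    retained.
    """
    if center not in net.nodes:
        raise KeyError(f"center node {center!r} not in network")
    keep = {center} | set(net.targets_of(center))
    edges = {(s, t) for s, t in net.edges if s in keep and t in keep}
    return RegulatoryNetwork(edges, label=f"{net.label}|ego_{center}" if net.label else f"ego_{center}")


def restrict_targets(net: RegulatoryNetwork, keep: Iterable[str]) -> RegulatoryNetwork:
    """Restrict a network to a gene list, keeping all TFs as regulators.

    An edge survives iff its target is either in ``keep`` or is itself a TF
    of ``net`` — so the regulatory cascade between TFs is preserved even
    when the TFs are not on the list (the gene-list restriction is about
    *non-TF* targets, e.g. mitochondrially annotated genes).
    """
    keep_set = set(keep)
    tfs = net.tf_ids
    edges = {(s, t) for s, t in net.edges if t in keep_set or t in tfs}
    if not edges:
        warnings.warn("gene-list restriction produced an empty network", stacklevel=2)
    label = f"{net.label}|restricted" if net.label else "restricted"
    return RegulatoryNetwork(edges, label=label)
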