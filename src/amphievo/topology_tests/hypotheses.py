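"""Bundled backbone hypotheses and their expansion to resolved topologies."""

from __future__ import annotations

import importlib.resources
import re

from amphievo.core.tree import Tree


def load_hypotheses() -> dict[str, str]:
    """Label -> backbone newick template with group tokens as leaves."""
    path = importlib.resources.files("amphievo") / "data" / "hypotheses.nwk"
    out = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, nwk = line.split(None, 1)
        out[label] = nwk.strip()
    return out


def expand_hypothesis(template: str, group_clades: dict[str, str]) -> Tree:
    """Substitute each group token in a backbone template by a resolved clade.

    ``group_clades`` maps token -> newick clade string WITHOUT the trailing
    semicolon (a single taxon name is fine).
    """
    nwk = template
    for token, clade in group_clades.items():
        clade = clade.rstrip(";").strip()
        nwk = re.sub(rf"\b{re.escape(token)}\b", clade, nwk)
    return Tree.from_newick(nwk)
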