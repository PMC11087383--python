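"""Published candidate-TCR characteristics shipped as package data.

The source study reported, for each of two lung-adenocarcinoma patients,
the top-3 TCR clonotypes under three ranking keys (mean normalized IFNG,
mean normalized TNFRSF9, mean activation score), with their V/(D)/J calls,
CDR3 amino-acid sequences and per-key ranks. Nucleotide sequences were not
printed, so clonotype identity here is the tuple of CDR3 amino-acid
sequences plus V/(D)/J segment names of both chains — sufficient to
deduplicate the printed panel (the top IFNG and top TNFRSF9 clonotype
coincide in both patients, so six single-marker selections collapse to
five engineered TCRs per patient).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ranking import CandidatePanel, select_candidate_panel

GROUP_TO_KEY = {"IFN": "IFNG", "41BB": "TNFRSF9", "activation": "SCORE"}


def load_published_candidates() -> pd.DataFrame:
    """The printed candidate table as a DataFrame (one row per selection)."""
    ref = resources.files("tcrscreen.data") / "published_candidates.tsv"
    with resources.as_file(ref) as path:
        # keep_default_na so the printed "None" D-segment stays a literal string
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["clonotype_id"] = (
        df[["CDR3_alpha", "TRAV", "TRAJ", "CDR3_beta", "TRBV", "TRBD", "TRBJ"]]
        .agg("|".join, axis=1)
    )
    return df


def published_ranked_tables(patient: str, groups=("IFN", "41BB", "activation")) -> dict[str, pd.DataFrame]:
    """Per-key ranked tables (top-3 only, as printed) for one patient."""
    df = load_published_candidates()
    df = df[df["patient"] == patient]
    if df.empty:
        raise ValueError(f"unknown patient {patient!r}")
    value_col = {"IFN": "norm_IFNG", "41BB": "norm_TNFRSF9", "activation": "activation_score"}
    out: dict[str, pd.DataFrame] = {}
    for grp in groups:
        sub = df[df["group"] == grp].sort_values("rank_in_group")
        out[GROUP_TO_KEY[grp]] = pd.DataFrame(
            {
                "clonotype_id": sub["clonotype_id"].to_list(),
                "mean": sub[value_col[grp]].to_list(),
                "n_cells": sub["n_cells"].to_list(),
                "rank": sub["rank_in_group"].to_list(),
                "key": GROUP_TO_KEY[grp],
            }
        )
    return out


def published_panel(patient: str, groups=("IFN", "41BB"), k: int = 3) -> CandidatePanel:
    """Deduplicated candidate panel from the printed per-key top-3 lists.

    With the default single-marker groups this reproduces the study's panel
    of five engineered TCRs per patient.
    """
    return select_candidate_panel(published_ranked_tables(patient, groups), k=k)
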