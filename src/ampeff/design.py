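"""Optional integration with the Primer3 primer-design executable.

When ``primer3_core`` is on PATH, candidate primer pairs can be designed
for a template and ranked by predicted efficiency.  The Boulder-IO
(tag=value) parsing is independent of the executable so that designer
output can be scored even where the program itself is unavailable.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import pandas as pd

from .errors import FeatureUnavailableError
from .gam import EfficiencyModel, predict_efficiency
from .io import ParseError
from .seqfeatures import PrimerPair, extract_features, features_to_frame

__all__ = [
    "PrimerCandidate",
    "build_boulder_input",
    "design_and_rank",
    "find_designer",
    "parse_boulder_output",
    "score_candidates",
]

DESIGNER_EXECUTABLE = "primer3_core"


@dataclass(frozen=True)
class PrimerCandidate:
    """One designed primer pair with its product coordinates on the template."""

    index: int
    forward: str
    reverse: str
    product_start: int  # 0-based start of the forward primer
    product_size: int


def find_designer() -> str | None:
    """Path of the primer-design executable, or None if absent."""
    return shutil.which(DESIGNER_EXECUTABLE)


def build_boulder_input(seq_id: str, sequence: str, n_candidates: int = 5) -> str:
    """Boulder-IO request asking the designer for *n_candidates* pairs."""
    return (
        f"SEQUENCE_ID={seq_id}\n"
        f"SEQUENCE_TEMPLATE={sequence}\n"
        f"PRIMER_NUM_RETURN={n_candidates}\n"
        "PRIMER_TASK=generic\n"
        "=\n"
    )


def parse_boulder_output(text: str) -> list[PrimerCandidate]:
    """Parse designer Boulder-IO output into primer candidates.

    Only the first record (up to the ``=`` terminator) is read.  Returns an
    empty list when the designer found no acceptable pair.
    """
    tags: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if line == "=":
            break
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"malformed Boulder-IO line {line!r}")
        key, _, value = line.partition("=")
        tags[key] = value
    if "PRIMER_ERROR" in tags:
        raise ParseError(f"designer error: {tags['PRIMER_ERROR']}")
    n = int(tags.get("PRIMER_PAIR_NUM_RETURNED", 0))
    candidates = []
    for i in range(n):
        try:
            fwd = tags[f"PRIMER_LEFT_{i}_SEQUENCE"]
            rev = tags[f"PRIMER_RIGHT_{i}_SEQUENCE"]
            left = tags[f"PRIMER_LEFT_{i}"]          # "start,length"
            size = int(tags[f"PRIMER_PAIR_{i}_PRODUCT_SIZE"])
        except KeyError as exc:
            raise ParseError(f"candidate {i}: missing tag {exc}") from exc
        start = int(left.split(",")[0])
        candidates.append(PrimerCandidate(i, fwd, rev, start, size))
    return candidates


def run_designer(seq_id: str, sequence: str, n_candidates: int = 5) -> list[PrimerCandidate]:
    """Call the external designer; raises FeatureUnavailableError if absent."""
    exe = find_designer()
    if exe is None:
        raise FeatureUnavailableError(
            f"primer design requires the {DESIGNER_EXECUTABLE!r} executable on PATH; "
            "feature unavailable (everything else still works)"
        )
    proc = subprocess.run(
        [exe],
        input=build_boulder_input(seq_id, sequence, n_candidates),
        capture_output=True, text=True, check=False,
    )
    if proc.returncode != 0:
        raise ParseError(f"designer exited with {proc.returncode}: {proc.stderr.strip()}")
    return parse_boulder_output(proc.stdout)


def score_candidates(
    template: str,
    candidates: list[PrimerCandidate],
    model: EfficiencyModel,
    tm_method: str = "nearest_neighbor",
) -> pd.DataFrame:
    """Extract features for each candidate's product and predict efficiency.

    Returns one row per candidate, ranked by predicted efficiency
    (descending).  Empty input gives an empty table.
    """
    cols = ["candidate", "forward", "reverse", "productSize", "predicted",
            "clamped", "extrapolated"]
    if not candidates:
        return pd.DataFrame(columns=cols)
    records = {}
    for cand in candidates:
        product = template[cand.product_start : cand.product_start + cand.product_size]
        records[cand.index] = extract_features(
            product, PrimerPair(cand.forward, cand.reverse), tm_method=tm_method
        )
    feats = features_to_frame(records)
    preds = predict_efficiency(model, feats)
    out = pd.DataFrame(
        {
            "candidate": [c.index for c in candidates],
            "forward": [c.forward for c in candidates],
            "reverse": [c.reverse for c in candidates],
            "productSize": [c.product_size for c in candidates],
            "predicted": preds["predicted"].to_numpy(),
            "clamped": preds["clamped"].to_numpy(),
            "extrapolated": preds["extrapolated"].to_numpy(),
        }
    )
    return out.sort_values("predicted", ascending=False).reset_index(drop=True)


def design_and_rank(
    seq_id: str, template: str, model: EfficiencyModel, n_candidates: int = 5
) -> pd.DataFrame:
    """Design candidates for *template* and rank them by predicted efficiency."""
    return score_candidates(template, run_designer(seq_id, template, n_candidates), model)
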