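"""Diagnosis-group to outcome-category mapping (CCS and CCSR schemes).

CCS groups ICD-9 discharge diagnoses; CCSR groups ICD-10 diagnoses and a
code may belong to several groups, so the non-respiratory definition carries
an explicit respiratory exclusion (RSP002-RSP006).
"""

from __future__ import annotations

__all__ = ["CCS_GROUPS", "CCSR_GROUPS", "CCSR_EXCLUSION", "map_outcome_groups"]

# CCS (ICD-9) group ids per outcome category.
_CCS_NON_RESP = set(range(2, 10)) | {76, 77, 78, 90, 135, 159, 197, 201, 248}
CCS_GROUPS = {
    "non_respiratory": _CCS_NON_RESP,
    "cns": {76, 77, 78},
    "intestinal": {135},
    "urinary": {159},
    "septicemia": {2},
}

# CCSR (ICD-10) group ids per outcome category.
def _rng(prefix: str, lo: int, hi: int) -> set:
    return {f"{prefix}{i:03d}" for i in range(lo, hi + 1)}


_CCSR_NON_RESP = (
    _rng("INF", 2, 4)
    | _rng("INF", 6, 11)
    | _rng("MUS", 1, 2)
    | {"MUS027"}
    | _rng("NVS", 1, 3)
    | {"GEN001", "SKN001", "DIG001"}
)
CCSR_GROUPS = {
    "non_respiratory": _CCSR_NON_RESP,
    "cns": _rng("NVS", 1, 3),
    "intestinal": {"DIG001"},
    "urinary": {"GEN001"},
    "septicemia": {"INF002"},
}

#: Respiratory CCSR groups: membership there removes a record from the
#: non-respiratory category (subtype membership is unaffected).
CCSR_EXCLUSION = _rng("RSP", 2, 6)


def map_outcome_groups(scheme: str, group_id_or_set) -> set:
    """Outcome categories containing the given diagnosis group(s).

    For CCSR input sets, any intersection with the respiratory exclusion
    removes ``non_respiratory`` from the result.
    """
    scheme = scheme.upper()
    if scheme == "CCS":
        table, exclusion = CCS_GROUPS, set()
        groups = (
            {group_id_or_set}
            if isinstance(group_id_or_set, int)
            else set(group_id_or_set)
        )
    elif scheme == "CCSR":
        table, exclusion = CCSR_GROUPS, CCSR_EXCLUSION
        groups = (
            {group_id_or_set}
            if isinstance(group_id_or_set, str)
            else set(group_id_or_set)
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r} (use 'CCS' or 'CCSR')")

    cats = {cat for cat, ids in table.items() if groups & ids}
    if groups & exclusion:
        cats.discard("non_respiratory")
    return cats
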