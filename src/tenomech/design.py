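"""Block-randomized allocation of tendon halves to technique groups.

Each hind limb contributes four extensor tendons: the lateral (I) and medial
(IV) tendons have the smaller caliber and serve as donors, the median
tendons (II and III) as recipients. Tendons are cut in half and a suture
pairs the proximal half of one tendon with the distal half of the other.
The plan is constructed balanced first — every donor x recipient tendon
combination appears equally often in every group, and group sizes are equal
— and randomness only permutes assignments within blocks, so no draw can
violate balance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from tenomech.io import ValidationError

__all__ = ["block_randomize", "validate_plan", "DONOR_TYPES", "RECIPIENT_TYPES"]

DONOR_TYPES = ("I", "IV")
RECIPIENT_TYPES = ("II", "III")

#: The two donor-recipient pairings a single limb can host (each limb has one
#: tendon of each type and forms two sutures).
_PATTERNS = (
    (("I", "II"), ("IV", "III")),
    (("I", "III"), ("IV", "II")),
)

PLAN_COLUMNS = ["suture_id", "limb_id", "tendon_type", "half", "role", "group"]


def block_randomize(n_limbs: int, groups: Sequence[str] = ("A", "B", "C"),
                    seed: int = 0) -> pd.DataFrame:
    """Generate a balanced, block-randomized allocation plan.

    Each limb yields two sutures (one per donor tendon). Feasibility requires
    ``n_limbs`` to be a multiple of ``2 * len(groups)``: half the limbs pair
    (I-II, IV-III), the other half (I-III, IV-II), and within each pairing
    pattern every combination must hit every group equally often. The plan is
    deterministic given ``seed`` (PCG64 generator); randomization covers the
    pattern assignment of limbs, the group order within blocks, and which
    tendon of a suture contributes its proximal half.

    Returns a tidy frame with two rows per suture (donor and recipient).
    """
    g = len(groups)
    if g < 2 or len(set(groups)) != g:
        raise ValidationError("need at least two distinct group labels")
    block = 2 * g
    if n_limbs <= 0 or n_limbs % block != 0:
        raise ValidationError(
            f"n_limbs={n_limbs} infeasible for {g} balanced groups; "
            f"smallest feasible count is {block} (and multiples thereof)")
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    suture_id = 0
    limb_ids = list(range(1, n_limbs + 1))
    for b in range(n_limbs // block):
        block_limbs = limb_ids[b * block:(b + 1) * block]
        # half the limbs of the block to each pairing pattern, at random
        order = rng.permutation(block)
        pattern_of = {}
        for j, limb in enumerate(block_limbs):
            pattern_of[limb] = _PATTERNS[0] if order[j] < g else _PATTERNS[1]
        # within each pattern, each combination column gets every group once,
        # in an independently shuffled order
        for pat in _PATTERNS:
            limbs_p = [l for l in block_limbs if pattern_of[l] is pat]
            for slot, (donor_t, recip_t) in enumerate(pat):
                group_order = [groups[i] for i in rng.permutation(g)]
                for limb, grp in zip(limbs_p, group_order):
                    suture_id += 1
                    # which side contributes the proximal half
                    donor_prox = bool(rng.integers(0, 2))
                    rows.append({"suture_id": suture_id, "limb_id": limb,
                                 "tendon_type": donor_t,
                                 "half": "proximal" if donor_prox else "distal",
                                 "role": "donor", "group": grp})
                    rows.append({"suture_id": suture_id, "limb_id": limb,
                                 "tendon_type": recip_t,
                                 "half": "distal" if donor_prox else "proximal",
                                 "role": "recipient", "group": grp})
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def validate_plan(plan: pd.DataFrame, groups: Sequence[str]) -> list[str]:
    """Independent balance checker; returns a list of violations (empty = valid).

    Checks: donors only from tendon types I/IV and recipients only from
    II/III; each suture pairs one proximal with one distal half; equal group
    sizes; every donor x recipient combination equally frequent within every
    group; no tendon half used twice.
    """
    problems: list[str] = []
    required = set(PLAN_COLUMNS)
    if not required <= set(plan.columns):
        return [f"missing columns {sorted(required - set(plan.columns))}"]

    bad_donor = plan[(plan.role == "donor") & ~plan.tendon_type.isin(DONOR_TYPES)]
    if len(bad_donor):
        problems.append(f"{len(bad_donor)} donor rows from non-donor tendon types")
    bad_recip = plan[(plan.role == "recipient") & ~plan.tendon_type.isin(RECIPIENT_TYPES)]
    if len(bad_recip):
        problems.append(f"{len(bad_recip)} recipient rows from non-recipient tendon types")

    for sid, sub in plan.groupby("suture_id"):
        if len(sub) != 2 or set(sub.role) != {"donor", "recipient"}:
            problems.append(f"suture {sid} is not one donor plus one recipient")
            continue
        if set(sub.half) != {"proximal", "distal"}:
            problems.append(f"suture {sid} does not pair a proximal with a distal half")
        if sub.group.nunique() != 1:
            problems.append(f"suture {sid} spans two groups")

    halves = plan[["limb_id", "tendon_type", "half"]]
    if halves.duplicated().any():
        problems.append("some tendon half is used in more than one suture")

    sutures = plan[plan.role == "donor"][["suture_id", "group"]]
    sizes = sutures.group.value_counts()
    if set(sizes.index) != set(groups) or sizes.nunique() != 1:
        problems.append(f"group sizes unequal or groups missing: {sizes.to_dict()}")

    combo = (plan.pivot_table(index="suture_id", columns="role",
                              values="tendon_type", aggfunc="first")
             .join(plan.groupby("suture_id").group.first()))
    counts = combo.groupby(["group", "donor", "recipient"]).size()
    full = len(groups) * len(DONOR_TYPES) * len(RECIPIENT_TYPES)
    if len(counts) != full or counts.nunique() != 1:
        problems.append("donor x recipient combinations not equally frequent per group")
    return problems
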