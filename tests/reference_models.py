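"""Literal, slow reference implementations of the cognitive-model update
equations, written independently of the package (plain Python floats and
dicts, one trial at a time).  Used as the oracle in equivalence tests.
"""

from __future__ import annotations

import math


def ref_softmax(scores):
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    z = sum(exps)
    return [e / z for e in exps]


# ---------------------------------------------------------------------------
# Reversal / two-stage first-stage families


def trace_bayes(params, trials):
    p_r, p_emit, beta = params["p_r"], params["p_emit"], params["beta"]
    pr1 = 0.5
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * pr1, beta * (1.0 - pr1)]))
        # likelihood of (s, r) under h=1 (S1 good) and h=2
        if s == 0:
            like1 = p_emit if r == 1 else 1 - p_emit
            like2 = (1 - p_emit) if r == 1 else p_emit
        else:
            like1 = (1 - p_emit) if r == 1 else p_emit
            like2 = p_emit if r == 1 else 1 - p_emit
        post = like1 * pr1 / (like1 * pr1 + like2 * (1 - pr1))
        pr1 = (1 - p_r) * post + p_r * (1 - post)
    return out


def trace_mf1(params, trials):
    alpha, beta = params["alpha"], params["beta"]
    q = {0: 0.0, 1: 0.0}          # anticorrelated, maintained explicitly
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[0], beta * q[1]]))
        u = 1 - a
        q_a = q[a] + alpha * (r - q[a])
        q_u = q[u] - alpha * (r + q[u])
        q = {a: q_a, u: q_u}
    return out


def trace_mfn(params, trials, n, forgetting):
    alpha, beta = params["alpha"], params["beta"]
    q = {i: 0.0 for i in range(n)}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[i] for i in range(n)]))
        for i in range(n):
            if i == a:
                q[i] = q[i] + alpha * (r - q[i])
            elif forgetting == "to_zero":
                q[i] = params["forget"] * q[i]
            elif forgetting == "to_mean":
                q[i] = params["forget"] * q[i] + (1 - params["forget"]) * 0.5
    return out


def trace_mf2_drift(params, trials):
    a0, D1, b, beta = params["alpha0"], params["D1"], params["b"], params["beta"]
    q = {0: 0.0, 1: 0.0}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[0], beta * q[1]]))
        u = 1 - a
        if r == 1:
            q = {a: D1 * q[a] + 1.0, u: q[u] - b}
        else:
            q = {a: q[a] + a0 * (q[u] - q[a]), u: q[u]}
    return out


def trace_mf_inertia(params, trials, independent):
    alpha, beta = params["alpha"], params["beta"]
    ap, k = params["alpha_pers"], params["k_pers"]
    q = {0: 0.0, 1: 0.0}
    x = {0: 0.0, 1: 0.0}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * (q[i] + x[i]) for i in (0, 1)]))
        u = 1 - a
        if independent:
            q[a] = q[a] + alpha * (r - q[a])
        else:
            qa = q[a] + alpha * (r - q[a])
            qu = q[u] - alpha * (r + q[u])
            q = {a: qa, u: qu}
        xa = x[a] + ap * (k - x[a])
        xu = x[u] - ap * (k + x[u])
        x = {a: xa, u: xu}
    return out


def trace_rac8(params, trials):
    alpha, beta = params["alpha"], params["beta"]
    q = {(aug, a): 0.0 for aug in range(4) for a in (0, 1)}
    aug = 0                        # previous (state, reward) combo; starts (S1, 0)
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[(aug, 0)], beta * q[(aug, 1)]]))
        q[(aug, a)] = q[(aug, a)] + alpha * (r - q[(aug, a)])
        aug = 2 * s + (1 if r == 1 else 0)
    return out


def trace_mfq0(params, trials):
    alpha, beta = params["alpha"], params["beta"]
    q = {0: 0.0, 1: 0.0}
    v = {0: 0.0, 1: 0.0}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[0], beta * q[1]]))
        q[a] = q[a] + alpha * (v[s] - q[a])
        v[s] = v[s] + alpha * (r - v[s])
    return out


def trace_mb1(params, trials, p_common=0.8):
    alpha, beta = params["alpha"], params["beta"]
    v = {0: 0.0, 1: 0.0}
    out = []
    for (a, s, r) in trials:
        qmb = [p_common * v[0] + (1 - p_common) * v[1],
               (1 - p_common) * v[0] + p_common * v[1]]
        out.append(ref_softmax([beta * qmb[0], beta * qmb[1]]))
        u = 1 - s
        va = v[s] + alpha * (r - v[s])
        vu = v[u] - alpha * (r + v[u])
        v = {s: va, u: vu}
    return out


def trace_mb2(params, trials, forgetting, p_common=0.8):
    alpha, beta = params["alpha"], params["beta"]
    v = {0: 0.0, 1: 0.0}
    out = []
    for (a, s, r) in trials:
        qmb = [p_common * v[0] + (1 - p_common) * v[1],
               (1 - p_common) * v[0] + p_common * v[1]]
        out.append(ref_softmax([beta * qmb[0], beta * qmb[1]]))
        u = 1 - s
        v[s] = v[s] + alpha * (r - v[s])
        if forgetting:
            v[u] = params["forget"] * v[u]
    return out


def trace_mb_mix(params, trials, p_common=0.8):
    alpha, amb, w, beta = (params["alpha"], params["alpha_mb"], params["w"],
                           params["beta"])
    q1 = 0.0
    v1 = 0.0
    out = []
    for (a, s, r) in trials:
        qmb1 = (2 * p_common - 1) * v1
        net1 = (1 - w) * q1 + w * qmb1
        out.append(ref_softmax([beta * net1, -beta * net1]))
        ca = 1.0 if a == 0 else -1.0
        cs = 1.0 if s == 0 else -1.0
        q1 = q1 + alpha * (ca * r - q1)
        v1 = v1 + amb * (cs * r - v1)
    return out


# ---------------------------------------------------------------------------
# n-armed families


def trace_mfn_forget_pers(params, trials, n):
    alpha, D, beta = params["alpha"], params["forget"], params["beta"]
    dp, k = params["D_pers"], params["k_pers"]
    q = {i: 0.0 for i in range(n)}
    x = {i: 0.0 for i in range(n)}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * (q[i] + x[i]) for i in range(n)]))
        for i in range(n):
            if i == a:
                q[i] = q[i] + alpha * (r - q[i])
                x[i] = dp * x[i] + k
            else:
                q[i] = D * q[i]
                x[i] = dp * x[i]
    return out


def trace_mfn_utility(params, trials, n=3):
    ac, au, beta = params["alpha_c"], params["alpha_u"], params["beta"]
    q = {i: 0.0 for i in range(n)}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[i] for i in range(n)]))
        uc = params["U_c1"] if r == 1 else params["U_c0"]
        uu = params["U_u1"] if r == 1 else params["U_u0"]
        for i in range(n):
            if i == a:
                q[i] = q[i] + ac * (uc - q[i])
            else:
                q[i] = q[i] + au * (uu - q[i])
    return out


def trace_mfn_refpoint(params, trials, n=4, reduced=False):
    ac, au, beta = params["alpha_c"], params["alpha_u"], params["beta"]
    bc = ac if reduced else params["beta_c"]
    bu = au if reduced else params["beta_u"]
    Rc, Ru = params["R_c"], params["R_u"]
    q = {i: 0.0 for i in range(n)}
    out = []
    for (a, s, r) in trials:
        out.append(ref_softmax([beta * q[i] for i in range(n)]))
        for i in range(n):
            if i == a:
                q[i] = (1 - ac) * q[i] + bc * (r - Rc)
            else:
                q[i] = (1 - au) * q[i] + bu * (r - Ru)
    return out


# ---------------------------------------------------------------------------
# Transition-reversal composite models


def trace_akam(params, trials, components, forget_q, forget_t,
               multi_pers, motor_pers):
    aQ = params["alpha_Q"]
    fQ = params.get("f_Q", 0.0)
    v = {0: 0.0, 1: 0.0}
    qmf = {0: 0.0, 1: 0.0}
    p1 = {0: 0.5, 1: 0.5}           # P(S1 | A_i)
    qmo = {m: 0.0 for m in range(4)}  # motor action a + 2*s_prev
    xcp = 0.0
    xmocp = {0: 0.0, 1: 0.0}
    s_last = 0                       # most recent second-stage state
    xs = 0.0
    out = []
    for (a, s, r) in trials:
        # scores for this trial
        qnet = {0: 0.0, 1: 0.0}
        if "mf" in components:
            for i in (0, 1):
                qnet[i] += params["G_mf"] * qmf[i]
        if "mb" in components:
            for i in (0, 1):
                qnet[i] += params["G_mb"] * (p1[i] * v[0] + (1 - p1[i]) * v[1])
        if "motor" in components:
            for i in (0, 1):
                qnet[i] += params["G_mo"] * qmo[i + 2 * s_last]
        x2 = params["B_c"] + params["B_r"] * xs + params["P_c"] * xcp
        if motor_pers:
            x2 += params["P_m"] * xmocp[s_last]
        out.append(ref_softmax([qnet[0], qnet[1] + x2]))

        s_before = s_last            # s_{t-2} while processing trial t-1
        u_a, u_s = 1 - a, 1 - s
        v_prev = dict(v)
        v[s] = v[s] + aQ * (r - v[s])
        if forget_q:
            v[u_s] = (1 - fQ) * v[u_s]
        if "mf" in components:
            al, lam = params["alpha"], params["lam"]
            target = lam * r + (1 - lam) * v_prev[s]
            qmf[a] = qmf[a] + al * (target - qmf[a])
            if forget_q:
                qmf[u_a] = (1 - fQ) * qmf[u_a]
        if "mb" in components:
            aT = params["alpha_T"]
            p1[a] = (1 - aT) * p1[a] + aT * (1.0 if s == 0 else 0.0)
            if forget_t:
                fT = params["f_T"]
                p1[u_a] = p1[u_a] + fT * (0.5 - p1[u_a])
        if "motor" in components:
            al, lam = params["alpha"], params["lam"]
            mo = a + 2 * s_before
            target = lam * r + (1 - lam) * v_prev[s_before]
            new_mo = qmo[mo] + al * (target - qmo[mo])
            if forget_q:
                for m in qmo:
                    qmo[m] = (1 - fQ) * qmo[m]
            qmo[mo] = new_mo
        xt = -0.5 if a == 0 else 0.5
        ac = params["alpha_c"] if multi_pers else 1.0
        xcp = xcp + ac * (xt - xcp)
        if motor_pers:
            am = params["alpha_m"]
            xmocp[s_before] = xmocp[s_before] + am * (xt - xmocp[s_before])
        s_last = s
        xs = -0.5 if s == 0 else 0.5
    return out


# ---------------------------------------------------------------------------
# Original two-stage task (two policies per trial)


def trace_ots(params, trials, variant, p_common=0.7):
    """Returns (first-stage policies, second-stage policies)."""
    anticorr = variant in ("mf3", "mb2", "mix3", "utility3")
    has_mf = variant in ("mf3", "mix3", "mf6", "mix6", "utility3")
    has_mb = variant in ("mb2", "mix3", "mb4", "mix6")
    b1, b2 = params["beta1"], params["beta2"]
    a2p = params["alpha2"]
    if anticorr:
        q0 = 0.0
        qs = {0: 0.0, 1: 0.0}       # q1, q2 (value of option index 0)
    else:
        q0 = {0: 0.0, 1: 0.0}
        qs = {0: {0: 0.0, 1: 0.0}, 1: {0: 0.0, 1: 0.0}}
    out1, out2 = [], []
    for (a, s, a2, r) in trials:
        # first-stage policy
        if variant == "utility3" or (has_mf and not has_mb):
            qmf = [q0, -q0] if anticorr else [q0[0], q0[1]]
            out1.append(ref_softmax([b1 * qmf[0], b1 * qmf[1]]))
        else:
            if anticorr:
                best = {st: abs(qs[st]) for st in (0, 1)}
            else:
                best = {st: max(qs[st][0], qs[st][1]) for st in (0, 1)}
            qmb = [p_common * best[0] + (1 - p_common) * best[1],
                   (1 - p_common) * best[0] + p_common * best[1]]
            if has_mf:
                w = params["w"]
                qmf = [q0, -q0] if anticorr else [q0[0], q0[1]]
                net = [(1 - w) * qmf[i] + w * qmb[i] for i in (0, 1)]
            else:
                net = qmb
            out1.append(ref_softmax([b1 * net[0], b1 * net[1]]))
        # second-stage policy at the arrived state s
        if anticorr:
            out2.append(ref_softmax([b2 * qs[s], -b2 * qs[s]]))
        else:
            out2.append(ref_softmax([b2 * qs[s][0], b2 * qs[s][1]]))

        # updates
        if variant == "utility3":
            a1p = params["alpha1"]
            u0 = 1.0 if r == 1 else params["U_1st_zero"]
            u_ch = 1.0 if r == 1 else params["U_2nd_zero"]
            u_ot = params["U_other"] if r == 1 else -params["U_other"]
            c0 = 1.0 if a == 0 else -1.0
            c2 = 1.0 if a2 == 0 else -1.0
            other = 1 - s
            qs[s] = qs[s] + a2p * (c2 * u_ch - qs[s])
            qs[other] = qs[other] + a2p * (c2 * u_ot - qs[other])
            q0 = q0 + a1p * (c0 * u0 - q0)
            continue
        if anticorr:
            c2 = 1.0 if a2 == 0 else -1.0
            qs[s] = qs[s] + a2p * (c2 * r - qs[s])
            q2_chosen = c2 * qs[s]
        else:
            qs[s][a2] = qs[s][a2] + a2p * (r - qs[s][a2])
            q2_chosen = qs[s][a2]
        if has_mf:
            a1p, lam = params["alpha1"], params["lam"]
            target = lam * r + (1 - lam) * q2_chosen
            if anticorr:
                c0 = 1.0 if a == 0 else -1.0
                q0 = q0 + a1p * (c0 * target - q0)
            else:
                q0[a] = q0[a] + a1p * (target - q0[a])
    return out1, out2
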