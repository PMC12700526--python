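"""Independent brute-force implementations of the event/outcome rules.

Plain-Python scans over samples, written directly from the rule statements
and kept free of any code from the package's kinematics module (only the
shared velocity estimate is reused, since the rules are defined on it).
Used to cross-check every detector on simulated trials.
"""

import math

import numpy as np

from moveholdlab.io import estimate_velocity


def _speed(tr, smooth_window=0.025):
    _, _, speed = estimate_velocity(tr, smooth_window)
    return speed


def onset_oracle(tr, threshold=3.5):
    speed = _speed(tr)
    for i in range(len(tr.t)):
        if speed[i] > threshold:
            return tr.t[i]
    return None


def end_oracle(tr, onset_t, threshold=3.5, radius=0.5):
    speed = _speed(tr)
    tx, ty = tr.meta.target_pos
    for i in range(len(tr.t)):
        if tr.t[i] <= onset_t:
            continue
        if math.hypot(tr.x[i] - tx, tr.y[i] - ty) <= radius and speed[i] < threshold:
            return tr.t[i]
    return None


def _index_at(tr, t0):
    for i in range(len(tr.t)):
        if tr.t[i] >= t0 - 1e-12:
            return i
    return len(tr.t) - 1


def chord_angle_oracle(tr, t0, chord=0.150):
    sx, sy = tr.meta.start_pos
    tx, ty = tr.meta.target_pos
    dx, dy = tx - sx, ty - sy
    i0 = _index_at(tr, t0)
    i1 = _index_at(tr, t0 + chord)
    cx, cy = tr.x[i1] - tr.x[i0], tr.y[i1] - tr.y[i0]
    if cx == 0 and cy == 0:
        return 0.0
    return math.degrees(math.atan2(dx * cy - dy * cx, dx * cx + dy * cy))


def theta_start_oracle(tr, threshold=3.5):
    onset = onset_oracle(tr, threshold)
    if onset is None:
        return None
    return chord_angle_oracle(tr, onset)


def theta_end_oracle(tr, threshold=3.5, approach=2.0):
    onset = onset_oracle(tr, threshold)
    if onset is None:
        return None
    tx, ty = tr.meta.target_pos
    for i in range(len(tr.t)):
        if tr.t[i] >= onset and math.hypot(tr.x[i] - tx, tr.y[i] - ty) <= approach:
            return chord_angle_oracle(tr, tr.t[i])
    return None


def path_length_oracle(tr, t0, t1):
    total = 0.0
    prev = None
    for i in range(len(tr.t)):
        if t0 - 1e-12 <= tr.t[i] <= t1 + 1e-12:
            if prev is not None:
                total += math.hypot(tr.x[i] - prev[0], tr.y[i] - prev[1])
            prev = (tr.x[i], tr.y[i])
    return total


def lateral_oracle(tr):
    sx, sy = tr.meta.start_pos
    tx, ty = tr.meta.target_pos
    norm = math.hypot(tx - sx, ty - sy)
    ux, uy = (tx - sx) / norm, (ty - sy) / norm
    lx, ly = -uy, ux
    vx, vy, _ = estimate_velocity(tr, 0.025)
    lat_pos = [(tr.x[i] - sx) * lx + (tr.y[i] - sy) * ly for i in range(len(tr.t))]
    lat_vel = [vx[i] * lx + vy[i] * ly for i in range(len(tr.t))]
    return np.array(lat_pos), np.array(lat_vel)


def pulse_oracle(tr, settle=2.0, persist=0.100):
    """(settling_time, max_lateral_dev, censored) by direct rule scan."""
    pulse_t = tr.events["pulse_onset"]
    lat_pos, lat_vel = lateral_oracle(tr)
    onset = onset_oracle(tr)
    end_t = end_oracle(tr, onset) if onset is not None else None
    if end_t is None:
        end_t = tr.t[-1]
    dt = np.median(np.diff(tr.t))
    n_persist = int(round(persist / dt)) + 1
    i_pulse = _index_at(tr, pulse_t)
    i_end = max(_index_at(tr, end_t), i_pulse)
    if tr.t[i_end] > end_t + 1e-12:
        i_end -= 1
    settling = None
    censored = False
    for i in range(i_pulse, i_end + 1):
        ok = True
        for j in range(i, min(i + n_persist, i_end + 1)):
            if abs(lat_vel[j]) >= settle:
                ok = False
                break
        if ok:
            settling = tr.t[i] - pulse_t
            censored = i + n_persist - 1 > i_end
            break
    if settling is None:
        settling = end_t - pulse_t
        censored = True
    sign = 1.0 if tr.meta.pulse_sign == "CCW" else -1.0
    max_dev = max(sign * lat_pos[i] for i in range(i_pulse, i_end + 1))
    return settling, max_dev, censored


def release_oracle(tr, settle=2.0, persist=0.100, dist_crit=2.0, cap=2.0,
                   cap_mode="impute_2s"):
    """(time, path, max_deviation, censored) by direct rule scan."""
    rel_t = tr.events["release_onset"]
    _, _, speed = estimate_velocity(tr, 0.025)
    tx, ty = tr.meta.target_pos
    th = math.radians(tr.meta.release_direction_deg + 180.0)
    ux, uy = math.cos(th), math.sin(th)
    dt = np.median(np.diff(tr.t))
    n_persist = int(round(persist / dt)) + 1
    i_rel = _index_at(tr, rel_t)
    if cap_mode == "uncapped":
        stop_t = tr.t[-1]
    else:
        stop_t = min(rel_t + cap, tr.t[-1])
    i_stop = _index_at(tr, stop_t)
    if tr.t[i_stop] > stop_t + 1e-12:
        i_stop -= 1
    dist = [math.hypot(tr.x[i] - tx, tr.y[i] - ty) for i in range(len(tr.t))]
    hit = None
    for i in range(i_rel, i_stop + 1):
        if dist[i] >= dist_crit:
            continue
        ok = True
        for j in range(i, min(i + n_persist, i_stop + 1)):
            if speed[j] >= settle:
                ok = False
                break
        if ok:
            hit = i
            break
    if hit is not None:
        time = tr.t[hit] - rel_t
        censored = False
        seg_end = hit
    else:
        censored = True
        seg_end = i_stop
        if cap_mode == "impute_2s":
            time = cap
        elif cap_mode == "exclude":
            time = float("nan")
        else:
            time = tr.t[i_stop] - rel_t
    path = path_length_oracle(tr, tr.t[i_rel], tr.t[seg_end])
    max_dev = max(
        (tr.x[i] - tx) * ux + (tr.y[i] - ty) * uy for i in range(i_rel, i_stop + 1)
    )
    return time, path, max_dev, censored
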