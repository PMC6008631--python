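"""Mobility of the shoulder mechanism by the Kutzbach-Grubler formula.

The closed girdle loop has three links (clavicle, scapula, thorax) joined
by two spherical joints (SC, AC) and one 4-DoF cylinder-plane pair (the
two-point scapulothoracic contact).  Adding the 3-DoF glenohumeral joint
and the humerus gives the whole shoulder.
"""

from shoulderkin import mobility

girdle = mobility(3, [3, 3, 4])
shoulder = mobility(4, [3, 3, 4, 3])
print(f"closed girdle loop: {girdle} DoF")   # 4: three inputs + one internal clavicle spin
print(f"whole shoulder:     {shoulder} DoF")  # girdle + 3-DoF glenohumeral joint
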