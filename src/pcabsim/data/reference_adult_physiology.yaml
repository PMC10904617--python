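# Bundled reference virtual subject: 70 kg healthy adult.
# Volumes and blood flows compiled from standard reference-human tables
# (organ weights at unit density; flows as fractions of a 6.5 L/min
# cardiac output). This file is a configuration artifact: comparisons of
# simulated outputs against published values are toleranced accordingly.
#
# Conventions:
#   - lung flow equals cardiac output (lung is perfused in series),
#   - liver flow is the hepatic-artery flow only; total liver perfusion is
#     hepatic artery plus portal drainage (gut, spleen, pancreas, stomach),
#   - rest_of_body closes the mass and flow balances.
body_weight_kg: 70.0
cardiac_output_L_h: 390.0
plasma_volume_L: 3.0
gut_lumen_radius_cm: 1.25
blood_volumes:
  venous: 3.4
  arterial: 1.7
tissues:
  lung:         {volume_L: 0.52,  flow_L_h: 390.0}
  heart:        {volume_L: 0.33,  flow_L_h: 15.6}
  brain:        {volume_L: 1.45,  flow_L_h: 46.8}
  muscle:       {volume_L: 29.0,  flow_L_h: 66.3}
  adipose:      {volume_L: 13.5,  flow_L_h: 19.5}
  skin:         {volume_L: 3.3,   flow_L_h: 22.6}
  spleen:       {volume_L: 0.19,  flow_L_h: 8.2}
  pancreas:     {volume_L: 0.1,   flow_L_h: 3.9}
  liver:        {volume_L: 1.8,   flow_L_h: 25.35}
  stomach:      {volume_L: 0.15,  flow_L_h: 3.9}
  gut:          {volume_L: 1.1,   flow_L_h: 57.0}
  bone:         {volume_L: 10.2,  flow_L_h: 19.5}
  kidney:       {volume_L: 0.31,  flow_L_h: 74.1}
  rest_of_body: {volume_L: 2.95,  flow_L_h: 27.25}
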