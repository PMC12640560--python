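# DBS lead catalog: vendor-nominal geometry for the lead models used in the
# experimental cohort.  Contact heights/gaps/diameters are the manufacturers'
# published nominal dimensions; they can be overridden via `build_lead(overrides=...)`.
#
# Conventions: lead frame is right-handed, +z from tip toward shaft, dimensions mm.
# Levels are numbered proximal->distal starting at 0 for the bottom (most distal)
# contact level.  Segmented levels list angular sectors as [start_deg, end_deg)
# measured about +z from the lead-frame +x axis.

MDT3387:
  vendor: Medtronic
  type: standard
  shaft_radius: 0.635
  tip_length: 1.5
  contact_height: 1.5
  contact_gap: 1.5
  levels:
    - [ring]
    - [ring]
    - [ring]
    - [ring]

MDT3389:
  vendor: Medtronic
  type: standard
  shaft_radius: 0.635
  tip_length: 1.5
  contact_height: 1.5
  contact_gap: 0.5
  levels:
    - [ring]
    - [ring]
    - [ring]
    - [ring]

BSC2201:
  vendor: Boston Scientific
  type: standard
  shaft_radius: 0.65
  tip_length: 1.1
  contact_height: 1.5
  contact_gap: 0.5
  levels:
    - [ring]
    - [ring]
    - [ring]
    - [ring]
    - [ring]
    - [ring]
    - [ring]
    - [ring]

# 1-3-3-1 steerable leads: bottom ring, two segmented levels of three sectors,
# top ring.  Sector spans are the vendor-nominal ~100 deg arcs with ~20 deg
# inter-segment insulation.
ABT6172:
  vendor: Abbott
  type: steerable
  shaft_radius: 0.635
  tip_length: 1.0
  contact_height: 1.5
  contact_gap: 0.5
  levels:
    - [ring]
    - [[0, 104], [120, 224], [240, 344]]
    - [[0, 104], [120, 224], [240, 344]]
    - [ring]

BSC2202:
  vendor: Boston Scientific
  type: steerable
  shaft_radius: 0.65
  tip_length: 1.1
  contact_height: 1.5
  contact_gap: 0.5
  levels:
    - [ring]
    - [[0, 100], [120, 220], [240, 340]]
    - [[0, 100], [120, 220], [240, 340]]
    - [ring]
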