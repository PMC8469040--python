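{
 "source": "published per-task ergonomic assessment of a hand-made cookware operation",
 "note": "printed_ev/printed_ec are the printed values; the row flagged eq1_inconsistent contradicts EV = D x RAL + V (recomputed EV = 6)",
 "tasks": [
  {
   "task_id": "preparing_sand",
   "name": "Preparing sand",
   "ral": 4,
   "duration_band": 1,
   "vibration": 0,
   "printed_ev": 4,
   "printed_ec": "medium",
   "eq1_inconsistent": false,
   "hazard_note": "loosening sand and breaking lumps with a spade/shovel (~2 kg), highly repetitive trunk and arm movements, lifts above shoulder height"
  },
  {
   "task_id": "preparing_flat_sand_surface",
   "name": "Preparing flat sand surface",
   "ral": 4,
   "duration_band": 2,
   "vibration": 0,
   "printed_ev": 8,
   "printed_ec": "high",
   "eq1_inconsistent": false,
   "hazard_note": "flattening a sand bed for the mould cavity, trunk flexed 60 deg or more, highly repetitive"
  },
  {
   "task_id": "loading_sand",
   "name": "Loading sand",
   "ral": 4,
   "duration_band": 1,
   "vibration": 0,
   "printed_ev": 4,
   "printed_ec": "medium",
   "eq1_inconsistent": false,
   "hazard_note": "loading sand onto the cookware replica, trunk 20-60 deg flexion, at times twisted or side-bent, spade loads 3-5 kg"
  },
  {
   "task_id": "creating_mould_cavity",
   "name": "Creating mould cavity",
   "ral": 4,
   "duration_band": 3,
   "vibration": 0,
   "printed_ev": 12,
   "printed_ec": "high",
   "eq1_inconsistent": false,
   "hazard_note": "packing and ramming sand with a shovel and a 7 kg rod, kneeling, lifts above shoulder height"
  },
  {
   "task_id": "dismantling_and_sprinkling_ash",
   "name": "Dismantling the mould cavity and sprinkling ash",
   "ral": 3,
   "duration_band": 1,
   "vibration": 0,
   "printed_ev": 3,
   "printed_ec": "medium",
   "eq1_inconsistent": false,
   "hazard_note": "dismantling the casting box and sprinkling ash, arm across the midline, deviated wrist, squatting or kneeling, loads up to 20+ kg"
  },
  {
   "task_id": "liquifying_metal",
   "name": "Liquifying metal",
   "ral": 3,
   "duration_band": 2,
   "vibration": 0,
   "printed_ev": 3,
   "printed_ec": "medium",
   "eq1_inconsistent": true,
   "hazard_note": "melting scrap metal at the furnace, trunk moderately flexed, repetitive arm/wrist movements, ~10 kg handled"
  },
  {
   "task_id": "transporting_pouring_molten_metal",
   "name": "Transporting and pouring molten metal into the mould",
   "ral": 3,
   "duration_band": 1,
   "vibration": 0,
   "printed_ev": 3,
   "printed_ec": "medium",
   "eq1_inconsistent": false,
   "hazard_note": "carrying a long-handled cup-shaped bowl (11-20 kg), back, arms and wrist static during pouring, load static over a minute"
  },
  {
   "task_id": "breaking_the_mould",
   "name": "Breaking the mould",
   "ral": 3,
   "duration_band": 1,
   "vibration": 0,
   "printed_ev": 3,
   "printed_ec": "medium",
   "eq1_inconsistent": false,
   "hazard_note": "watering and breaking the mould to free the casting, trunk 20-60 deg flexion, highly repetitive, spade loads 3-5 kg"
  },
  {
   "task_id": "removing_defects",
   "name": "Removing defects",
   "ral": 4,
   "duration_band": 4,
   "vibration": 1,
   "printed_ev": 17,
   "printed_ec": "very_high",
   "eq1_inconsistent": false,
   "hazard_note": "grinding off excess metal with a sanding machine (20+ kg), trunk flexed/twisted, squatting, highly repetitive, vibration"
  }
 ]
}
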