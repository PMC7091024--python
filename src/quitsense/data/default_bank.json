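[
  {"id": "prep-001", "category": "prequit_prep", "text": "Your quit date is coming up. Start noticing when and where you usually smoke so you can plan around those moments."},
  {"id": "prep-002", "category": "prequit_prep", "text": "Before your quit date, clear cigarettes, lighters, and ashtrays out of your home, car, and workplace."},
  {"id": "prep-003", "category": "prequit_prep", "text": "Think of one person you can call for support on your quit date and let them know your plan."},
  {"id": "low-001", "category": "low_risk", "text": "You are doing well right now. Remind yourself why you decided to quit and picture the payoff."},
  {"id": "low-002", "category": "low_risk", "text": "Every hour smoke-free lets your body recover. Keep water or sugar-free gum handy for the next urge."},
  {"id": "low-003", "category": "low_risk", "text": "Staying quit is easier with small rewards. Plan something pleasant for the end of the day."},
  {"id": "hr-urge-001", "category": "high_risk_urge", "text": "Urges peak and pass within a few minutes. Ride this one out: breathe slowly and count each breath until it fades."},
  {"id": "hr-urge-002", "category": "high_risk_urge", "text": "A strong urge is a signal to change what you are doing. Stand up, move to another room, and give your hands something to do."},
  {"id": "hr-urge-003", "category": "high_risk_urge", "text": "Delay beats the urge: tell yourself you will wait 10 minutes. Most urges are gone before the time is up."},
  {"id": "hr-stress-001", "category": "high_risk_stress", "text": "Feeling stressed is a common lapse trigger. Try a slow breathing cycle: in for four counts, out for six, ten times."},
  {"id": "hr-stress-002", "category": "high_risk_stress", "text": "Stress passes whether or not you smoke — smoking just adds another problem. Step away from the situation for five minutes if you can."},
  {"id": "hr-stress-003", "category": "high_risk_stress", "text": "When tension rises, drop your shoulders, unclench your jaw, and take three slow breaths before deciding anything."},
  {"id": "hr-avail-001", "category": "high_risk_availability", "text": "Cigarettes within reach make lapses much more likely. Move them out of sight or give them to someone else to hold."},
  {"id": "hr-avail-002", "category": "high_risk_availability", "text": "Easy access is a trap. Change your surroundings: leave the room, take a walk, or put distance between you and the pack."},
  {"id": "hr-avail-003", "category": "high_risk_availability", "text": "If someone near you has cigarettes, ask them not to offer you one. Protecting your quit is worth the awkward moment."},
  {"id": "hr-mot-001", "category": "high_risk_motivation", "text": "Motivation dips are normal and temporary. Re-read your own reasons for quitting — they have not changed."},
  {"id": "hr-mot-002", "category": "high_risk_motivation", "text": "You do not need to feel motivated to stay quit for the next hour. Act first; the motivation usually follows."},
  {"id": "hr-mot-003", "category": "high_risk_motivation", "text": "Think about who benefits when you stay quit today. Keeping that person in mind can carry you through a low moment."},
  {"id": "rec-001", "category": "lapse_recovery", "text": "A slip is not a failure — it is information. What was happening right before? Use it to plan for next time."},
  {"id": "rec-002", "category": "lapse_recovery", "text": "One cigarette does not undo your progress. The most important step is the next one: get back to not smoking now."},
  {"id": "rec-003", "category": "lapse_recovery", "text": "Many successful quitters lapse along the way. Treat this as practice, set the slip aside, and restart your quit right now."},
  {"id": "daily-001", "category": "daily_treatment", "text": "Your quit date is tomorrow. Get rid of any remaining cigarettes tonight and set out your patch for the morning."},
  {"id": "daily-002", "category": "daily_treatment", "text": "Today's tip: put on your patch at the same time every morning so it becomes automatic."},
  {"id": "daily-003", "category": "daily_treatment", "text": "Checking in daily keeps your quit on track. Take a moment to notice one benefit you have felt since quitting."},
  {"id": "gum-001", "category": "gum_prompt", "text": "Chewing a piece of nicotine gum right now may reduce your risk for smoking. Will you chew a piece of nicotine gum right now?"},
  {"id": "gum-002", "category": "gum_prompt", "text": "Nicotine gum works best at moments like this one. Chew a piece slowly and park it against your cheek."},
  {"id": "gum-003", "category": "gum_prompt", "text": "This is a good moment for nicotine gum. Use a piece now to take the edge off your risk."}
]
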