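{
  "_comment": "Phrase catalog for rendered reports. Slots use $name placeholders (string.Template). Standing phrases (quartile_*) are chosen by quartile cut points computed within the network: top = value >= 75th percentile, high = >= 50th, mid = >= 25th, low = below. Edit wording here; the code only fills slots.",
  "personal_data": "$name is a $sex student of class $class at school $school.",
  "personal_data_minimal": "$name is a student in this study group.",
  "risk_band": "The alcohol-use screening places $name in $band (score $total of $max). Recommended intervention: $action.",
  "risk_missing": "No alcohol-use screening score is available for $name; the risk section is omitted.",
  "friendship_named": "Within the $relation network, $name is named by $named_by classmates and names $names_out of them.",
  "friendship_isolate": "Within the $relation network, $name receives no nominations and names no one.",
  "friendship_community": "$name belongs to a group of $community_size students who are closely connected among themselves.",
  "consumption_band_context": "$name's drinking-risk category ($band) is shared by $band_peers of the $n_total students in the group.",
  "consumption_no_band": "No drinking-risk category is available for $name.",
  "quartile_top": "among the highest in the group",
  "quartile_high": "above the middle of the group",
  "quartile_mid": "around the middle of the group",
  "quartile_low": "among the lowest in the group",
  "measure_popularity": "How often $name is named by others is $standing.",
  "measure_influence": "$name's capacity to influence classmates is $standing.",
  "measure_mediation": "$name's role as a go-between connecting classmates is $standing.",
  "mediators_intro": "Information can best reach $name through: $names.",
  "mediators_none": "No classmate stands between $name and the rest of the group.",
  "influencers_intro": "The classmates most likely to influence $name are: $names.",
  "influencers_none": "$name names no classmates, so no personal influencers can be listed.",
  "group_overview": "The group has $n_nodes students and $n_edges named relationships; $density_pct% of all possible relationships are present.",
  "group_reciprocity": "$reciprocity_pct% of nominations are returned by the person named.",
  "group_communities": "The students form $n_communities distinct friendship groups (sizes: $sizes).",
  "group_assortativity_pos": "Students tend to form relationships with classmates whose drinking scores resemble their own (similarity $assortativity).",
  "group_assortativity_neg": "Students tend to form relationships with classmates whose drinking scores differ from their own (similarity $assortativity).",
  "group_assortativity_none": "Relationships show no clear pattern with respect to drinking scores.",
  "group_correlation": "Across students, $a and $b scores show a correlation of $r.",
  "group_degenerate": "This group has fewer than two members; no group description can be produced."
}
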