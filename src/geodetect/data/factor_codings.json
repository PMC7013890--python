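{
  "zones": [
    [1, "City Center zone"],
    [2, "Western coastal zone"],
    [3, "Midland zone"],
    [4, "Eastern zone"],
    [5, "Eastern coastal zone"]
  ],
  "seasons": [
    [1, "Spring (March-May)"],
    [2, "Summer (June-September)"],
    [3, "Autumn (October-November)"],
    [4, "Winter (December-February)"]
  ],
  "day_of_week": [
    [1, "Monday"],
    [2, "Tuesday"],
    [3, "Wednesday"],
    [4, "Thursday"],
    [5, "Friday"],
    [6, "Saturday"],
    [7, "Sunday"]
  ],
  "time_interval": [
    [1, "00:00-06:59 (midnight to dawn)"],
    [2, "07:00-08:59 (morning rush hours)"],
    [3, "09:00-11:59 (morning working hours)"],
    [4, "12:00-17:29 (afternoon working hours)"],
    [5, "17:30-19:29 (afternoon rushing hours)"],
    [6, "19:30-23:59 (nighttime)"]
  ],
  "road_type": [
    [1, "Highway"],
    [2, "Urban Expressway"],
    [3, "First-class highway"],
    [4, "Second-class highway"],
    [5, "Third-class highway"],
    [6, "Fourth-class highway"],
    [7, "Substandard road"],
    [8, "Branch urban road"],
    [9, "Road in public parking"],
    [10, "Road in public square"],
    [11, "Road in community"],
    [12, "Other road"]
  ],
  "road_line_style": [
    [1, "Straight"],
    [2, "General curve"],
    [3, "General slope"],
    [4, "General curve and general slope"],
    [5, "Steep slope"],
    [6, "Sharp curve"],
    [7, "General curve and steep slope"],
    [8, "General slope and sharp curve"],
    [9, "Sharp curve and steep slope"]
  ],
  "road_section_type": [
    [1, "Ordinary section"],
    [2, "Plane intersection"],
    [3, "Bridge"],
    [4, "Access"],
    [5, "Internal section"],
    [6, "Elevated section"],
    [7, "Ramp"],
    [8, "Tunnel"],
    [9, "Narrow section"]
  ],
  "pavement_material": [
    [1, "Asphalt concrete"],
    [2, "Cement concrete"],
    [3, "Sand"],
    [4, "Soil"],
    [5, "Others"]
  ],
  "pavement_condition": [
    [1, "Good"],
    [2, "Under construction"],
    [3, "Convex-concave"],
    [4, "Others"]
  ],
  "roadside_protection": [
    [1, "Green belt"],
    [2, "Border tree"],
    [3, "Concrete guardrail"],
    [4, "Protective pier (column)"],
    [5, "Metal guardrail"],
    [6, "Corrugated beam guardrail"],
    [7, "No protection"]
  ],
  "traffic_sign": [
    [0, "Bad or no"],
    [1, "Good"]
  ],
  "lighting_condition": [
    [1, "Daytime"],
    [2, "Street lighting at night"],
    [3, "No street lighting at night"]
  ],
  "weather": [
    [1, "Sunny"],
    [2, "Cloudy"],
    [3, "Rainy"],
    [4, "Others"]
  ],
  "topography": [
    [1, "Plain"],
    [2, "Hill"],
    [3, "Mountain"]
  ],
  "primary_cause": [
    [1, "Drunk driving"],
    [2, "Driving under the influence of alcohol"],
    [3, "Speeding over 50%"],
    [4, "Speeding below 50%"],
    [5, "Overloading"],
    [6, "Backing and wrong-way driving on highway"],
    [7, "License violation"],
    [8, "Illegal overtaking"],
    [9, "Traffic signal violation"],
    [10, "Traffic sign violation"],
    [11, "Wrong-way driving, not on highway"],
    [12, "Illegal road occupying"],
    [13, "Illegal backing"],
    [14, "Failure to give way properly"],
    [15, "Illegal meeting"],
    [16, "Helmet violation"],
    [17, "Illegal entering onto highway"],
    [18, "Vehicle defect"],
    [19, "Other violations"],
    [20, "Road facilities hazard"],
    [21, "Other non-illegal fault"]
  ],
  "whether_illegal": [
    [0, "Legal fault"],
    [1, "Illegal fault"]
  ],
  "responsible_party": [
    [1, "Pedestrians"],
    [2, "Non-motorized vehicles"],
    [3, "Minibuses"],
    [4, "Large and medium buses"],
    [5, "Light trucks"],
    [6, "Heavy trucks"],
    [7, "Motorcycles"],
    [8, "Other motor vehicles"],
    [9, "Traffic management authority"],
    [10, "Others"]
  ]
}
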