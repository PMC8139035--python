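intervention,year,percent
anxiety_basic,2020,40
anxiety_basic,2021,43.9
anxiety_basic,2022,47.5
anxiety_basic,2023,50.9
anxiety_basic,2024,54.1
anxiety_basic,2025,57.1
anxiety_basic,2026,59.9
anxiety_basic,2027,62.6
anxiety_basic,2028,65.2
anxiety_basic,2029,67.7
anxiety_basic,2030,70
anxiety_intensive,2020,1
anxiety_intensive,2021,12.6
anxiety_intensive,2022,17.3
anxiety_intensive,2023,20.4
anxiety_intensive,2024,22.6
anxiety_intensive,2025,24.4
anxiety_intensive,2026,25.8
anxiety_intensive,2027,27.1
anxiety_intensive,2028,28.2
anxiety_intensive,2029,29.1
anxiety_intensive,2030,30
depression_basic,2020,40
depression_basic,2021,43.0
depression_basic,2022,46.0
depression_basic,2023,49.0
depression_basic,2024,52.0
depression_basic,2025,55.0
depression_basic,2026,58.0
depression_basic,2027,61.0
depression_basic,2028,64.0
depression_basic,2029,67.0
depression_basic,2030,70
depression_intensive_first_episode,2020,1
depression_intensive_first_episode,2021,3.9
depression_intensive_first_episode,2022,6.8
depression_intensive_first_episode,2023,9.7
depression_intensive_first_episode,2024,12.6
depression_intensive_first_episode,2025,15.5
depression_intensive_first_episode,2026,18.4
depression_intensive_first_episode,2027,21.3
depression_intensive_first_episode,2028,24.2
depression_intensive_first_episode,2029,27.1
depression_intensive_first_episode,2030,30
depression_intensive_maintenance,2020,1
depression_intensive_maintenance,2021,3.9
depression_intensive_maintenance,2022,6.8
depression_intensive_maintenance,2023,9.7
depression_intensive_maintenance,2024,12.6
depression_intensive_maintenance,2025,15.5
depression_intensive_maintenance,2026,18.4
depression_intensive_maintenance,2027,21.3
depression_intensive_maintenance,2028,24.2
depression_intensive_maintenance,2029,27.1
depression_intensive_maintenance,2030,30
bipolar_intensive,2020,1
bipolar_intensive,2021,12.6
bipolar_intensive,2022,17.3
bipolar_intensive,2023,20.4
bipolar_intensive,2024,22.6
bipolar_intensive,2025,24.4
bipolar_intensive,2026,25.8
bipolar_intensive,2027,27.1
bipolar_intensive,2028,28.2
bipolar_intensive,2029,29.1
bipolar_intensive,2030,30
epilepsy_basic,2020,40
epilepsy_basic,2021,43.9
epilepsy_basic,2022,47.5
epilepsy_basic,2023,50.9
epilepsy_basic,2024,54.1
epilepsy_basic,2025,57.1
epilepsy_basic,2026,59.9
epilepsy_basic,2027,62.6
epilepsy_basic,2028,65.2
epilepsy_basic,2029,67.7
epilepsy_basic,2030,70
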