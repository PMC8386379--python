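feature,label,spearman_r,p_raw_label,p_adjusted_label,n_weeks,n_participants
voice_diary_sentiment,Voice diary sentiment,-0.26,<.001,<.001,2992,376
reported_sleep_duration,Reported sleep duration,-0.12,<.001,<.001,2797,308
ambient_audio_level,Ambient audio level,0.10,<.001,<.001,3618,368
ring_until_missed_minutes,Phone call ringing until missed minutes,0.10,<.001,<.001,3334,360
unique_location_clusters,Unique location clusters,-0.09,<.001,<.001,3623,379
voice_diary_words_per_minute,Voice diary words per minute,-0.09,<.001,<.001,2992,376
voice_diary_duration,Voice diary duration,0.08,<.001,<.001,3145,377
battery_percentage,Battery percentage,-0.07,<.001,<.001,3778,384
text_message_emoji_count,Text message emoji count,-0.07,<.001,<.001,3460,366
phone_call_count,Phone call count,0.07,<.001,<.001,3534,370
voice_diary_pauses_duration,Voice diary pauses duration,0.06,<.001,.001,3038,377
location_entropy,Location entropy,-0.06,<.001,<.001,3623,379
ambient_light_level,Ambient light level,-0.06,.001,.003,3122,325
outgoing_text_sentiment,Outgoing text message sentiment score,-0.06,.001,.003,3140,351
location_variance,Location variance,-0.06,<.001,.002,3623,379
phone_screen_on_minutes,Phone screen on minutes,0.05,.002,.003,3776,384
audio_system_volume,Audio system volume,-0.05,.002,.003,3779,384
charging_minutes,Charging minutes,0.04,.009,.02,3773,384
social_apps_usage,Social apps usage,-0.04,.02,.03,3346,357
time_spent_at_home,Time spent at home,0.04,.03,.049,3623,379
app_usage_missing,App usage missing,-0.03,.047,.08,3779,384
outgoing_phone_call_duration,Outgoing phone call duration,-0.03,.08,.12,3295,355
wellness_apps_usage,Wellness apps usage,0.03,.08,.12,3346,357
time_spent_at_hospital,Time spent at hospital,-0.03,.09,.12,3623,379
n_wifi_networks,Number of Wi-Fi networks,-0.03,.08,.12,3778,384
reported_sleep_duration_missing,Reported sleep duration missing,-0.03,.12,.16,3779,384
communication_apps_usage,Communication apps usage,0.02,.24,.30,3346,357
text_message_body_size,Text message body size,0.02,.26,.31,3460,366
ring_volume,Ring volume,0.02,.32,.37,3779,384
physically_active_minutes,Physically active minutes,-0.01,.38,.43,3612,382
audio_notification_volume,Audio notification volume,-0.01,.42,.46,3779,384
text_message_count,Text message count,0.01,.66,.71,3460,366
nearby_wifi_count,Nearby Wi-Fi networks count,0.01,.76,.78,3364,378
incoming_phone_call_duration,Incoming phone call duration,0.00,.97,.97,3217,354
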